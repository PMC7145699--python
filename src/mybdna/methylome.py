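"""Per-base methylation calls and the motif-methylation census.

5mC (cytosine methylated at ring carbon 5) and 6mA (adenine methylated on
the exocyclic N6 amine) are strand-specific chemical marks: a call is only
attributed to a motif when it sits at the right motif position *on the
motif strand*.  For the AACNDN element the biologically informative
positions are the two adenines (positions 1 and 2, 6mA) and the cytosine
of the AAC core (position 3, 5mC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import pandas as pd

from .motifs import MotifInstance, PromoterWindow
from .sequences import Genome

logger = logging.getLogger(__name__)

MOD_TYPES = ("5mC", "6mA")

#: the eight 5mC/6mA combination categories over motif positions (3, 1, 2)
CATEGORIES = (
    "unmethylated",
    "5mC-only",
    "6mA1-only",
    "6mA2-only",
    "5mC+6mA1",
    "5mC+6mA2",
    "6mA1+6mA2",
    "5mC+6mA1+6mA2",
)


@dataclass(frozen=True)
class MethylationCall:
    """A strand-specific per-base modification record."""

    chrom: str
    pos: int
    strand: str
    mod_type: str
    score: Optional[float] = None


def category_from_flags(m5c_pos3: bool, m6a_pos1: bool, m6a_pos2: bool) -> str:
    """The census category is a pure function of the three flags."""
    parts = []
    if m5c_pos3:
        parts.append("5mC")
    if m6a_pos1:
        parts.append("6mA1")
    if m6a_pos2:
        parts.append("6mA2")
    if not parts:
        return "unmethylated"
    if len(parts) == 1:
        return parts[0] + "-only"
    return "+".join(parts)


@dataclass
class MotifMethylationRecord:
    """A motif instance with its 5mC/6mA flags at positions 3, 1 and 2."""

    instance: MotifInstance
    m5c_pos3: bool
    m6a_pos1: bool
    m6a_pos2: bool

    @property
    def category(self) -> str:
        return category_from_flags(self.m5c_pos3, self.m6a_pos1, self.m6a_pos2)


def load_methylation(
    path: Union[str, Path],
    mod_type: str,
    min_score: Optional[float] = None,
) -> List[MethylationCall]:
    """Read single-base calls from a BED-like file.

    Expected columns: chrom, start, end, [name], [score], strand (tab or
    whitespace separated).  Every record must span exactly one base
    (end == start + 1); violations raise an error citing the line number.
    An optional minimum-score filter drops low-confidence calls.
    """
    if mod_type not in MOD_TYPES:
        raise ValueError(f"mod_type must be one of {MOD_TYPES}, got {mod_type!r}")
    calls: List[MethylationCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end != start + 1:
                raise ValueError(
                    f"{path}:{lineno}: methylation record must span one base "
                    f"(end == start + 1), got [{start},{end})"
                )
            score: Optional[float] = None
            strand = "+"
            if len(fields) >= 6:
                strand = fields[5]
                if fields[4] not in (".", ""):
                    score = float(fields[4])
            elif len(fields) == 5:
                if fields[4] not in (".", ""):
                    score = float(fields[4])
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if min_score is not None and score is not None and score < min_score:
                continue
            calls.append(MethylationCall(chrom, start, strand, mod_type, score))
    return calls


def write_methylation_bed(
    calls: Iterable[MethylationCall], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.strand)):
            score = "." if c.score is None else f"{c.score:g}"
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t.\t{score}\t{c.strand}\n")


def motif_position_coordinate(instance: MotifInstance, k: int) -> int:
    """Genomic coordinate of 1-based motif position ``k`` on the motif strand.

    '+' instance at start s: position k -> s + k - 1;
    '-' instance at [s, e): position k -> e - k.
    """
    if not 1 <= k <= instance.end - instance.start:
        raise ValueError(f"motif position {k} outside instance of length "
                         f"{instance.end - instance.start}")
    if instance.strand == "+":
        return instance.start + k - 1
    return instance.end - k


def attach_methylation(
    instances: Sequence[MotifInstance],
    calls: Iterable[MethylationCall],
) -> List[MotifMethylationRecord]:
    """Flag each motif instance with strand-matched calls at positions 1-3.

    Duplicate input calls are deduplicated by (chrom, pos, strand, mod_type).
    """
    call_set: Set[tuple] = {
        (c.chrom, c.pos, c.strand, c.mod_type) for c in calls
    }

    def has(inst: MotifInstance, k: int, mod: str) -> bool:
        pos = motif_position_coordinate(inst, k)
        return (inst.chrom, pos, inst.strand, mod) in call_set

    return [
        MotifMethylationRecord(
            inst,
            m5c_pos3=has(inst, 3, "5mC"),
            m6a_pos1=has(inst, 1, "6mA"),
            m6a_pos2=has(inst, 2, "6mA"),
        )
        for inst in instances
    ]


def tally_census(
    records: Sequence[MotifMethylationRecord],
    promoters: Optional[Sequence[PromoterWindow]] = None,
) -> Dict[str, int]:
    """Combination census over motif-methylation records.

    Returns total instance count, number of distinct genes with >= 1
    instance, the eight category counts, and the marginals (any-methylated,
    5mC at position 3, 6mA at positions 1 and 2).  Any-methylated always
    equals total minus unmethylated.
    """
    census: Dict[str, int] = {"total": len(records)}
    genes: Set[str] = set()
    for r in records:
        genes |= r.instance.gene_ids
    census["genes_with_instance"] = len(genes)
    for cat in CATEGORIES:
        census[cat] = 0
    m5c = m6a1 = m6a2 = 0
    for r in records:
        census[r.category] += 1
        m5c += r.m5c_pos3
        m6a1 += r.m6a_pos1
        m6a2 += r.m6a_pos2
    census["any_methylated"] = census["total"] - census["unmethylated"]
    census["5mC_pos3"] = m5c
    census["6mA_pos1"] = m6a1
    census["6mA_pos2"] = m6a2
    if promoters is not None and census["genes_with_instance"] > len(
        {p.gene_id for p in promoters}
    ):  # pragma: no cover - defensive
        raise AssertionError("more genes with instances than promoters supplied")
    return census


def write_census_tsv(census: Dict[str, int], path: Union[str, Path]) -> None:
    pd.Series(census, name="count").rename_axis("quantity").to_csv(path, sep="\t")


def read_census_tsv(path: Union[str, Path]) -> Dict[str, int]:
    s = pd.read_csv(path, sep="\t", index_col=0)["count"]
    return {str(k): int(v) for k, v in s.items()}
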