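"""Degenerate (IUPAC) motif scanning over promoter windows.

The WER binding element is the degenerate hexamer 5'-AACNDN-3' (D = A/G/T,
N = any base).  This module scans genome sequences — optionally restricted
to promoter windows — for any IUPAC pattern, on either or both strands.
A genomic N never matches any pattern code (including pattern N): an unknown
base must not create phantom motifs.

Coordinates are 0-based half-open throughout.  Minus-strand matches are
found by matching the pattern against the reverse complement and are
reported in genomic (plus-strand) coordinates with ``strand == '-'``;
``matched_seq`` is always the motif-strand sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .sequences import Genome, GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to the base set each one matches.
IUPAC_CODES: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


class MotifPattern:
    """A degenerate nucleotide pattern, e.g. ``MotifPattern("AACNDN")``.

    Each position code maps to a fixed base set (IUPAC); a genomic N matches
    no code.
    """

    def __init__(self, symbols: str):
        symbols = symbols.upper()
        if not symbols:
            raise ValueError("pattern must have length >= 1")
        for s in symbols:
            if s not in IUPAC_CODES:
                raise ValueError(f"unknown IUPAC code {s!r} in pattern {symbols!r}")
        self.symbols = symbols
        self.base_sets = [IUPAC_CODES[s] for s in symbols]

    def __len__(self) -> int:
        return len(self.symbols)

    def __repr__(self) -> str:
        return f"MotifPattern({self.symbols!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, MotifPattern) and self.symbols == other.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(self.symbols.translate(_IUPAC_COMPLEMENT)[::-1])

    def matches(self, seq: str) -> bool:
        """Position-wise set-membership match of an equal-length string."""
        if len(seq) != len(self.symbols):
            return False
        return all(b in s for b, s in zip(seq.upper(), self.base_sets))

    def regex(self) -> str:
        """Equivalent regular expression (N as explicit [ACGT] class)."""
        return "".join("[" + "".join(sorted(s)) + "]" for s in self.base_sets)


@dataclass(frozen=True)
class PromoterWindow:
    """The 0-L bp region upstream of a gene's TSS, clipped to the chromosome."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"promoter {self.gene_id}: need 0 <= start < end, "
                f"got [{self.start},{self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"promoter {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class MotifInstance:
    """A strand-aware genomic occurrence of a degenerate pattern."""

    chrom: str
    start: int
    end: int
    strand: str
    matched_seq: str
    gene_ids: Set[str] = field(default_factory=set)

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)


def load_annotation(path: Union[str, Path]) -> pd.DataFrame:
    """Read gene records from GFF3 (``*.gff3``/``*.gff``) or BED6.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand in
    0-based half-open coordinates (GFF3's 1-based closed intervals are
    converted on read, via pyranges).
    """
    import pyranges as pr

    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        df = pr.read_gff3(str(path)).df
        df = df[df.Feature == "gene"].copy()
        if "ID" in df.columns:
            gene_id = df["ID"].astype(str)
        else:  # pragma: no cover - malformed annotation
            gene_id = pd.Series([f"gene{i}" for i in range(len(df))], index=df.index)
        out = pd.DataFrame(
            {
                "gene_id": gene_id,
                "chrom": df.Chromosome.astype(str),
                "start": df.Start.astype(int),
                "end": df.End.astype(int),
                "strand": df.Strand.astype(str),
            }
        )
    else:
        df = pr.read_bed(str(path)).df
        out = pd.DataFrame(
            {
                "gene_id": df.Name.astype(str),
                "chrom": df.Chromosome.astype(str),
                "start": df.Start.astype(int),
                "end": df.End.astype(int),
                "strand": df.Strand.astype(str),
            }
        )
    return out.reset_index(drop=True)


def derive_promoters(
    annotation: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    upstream_length: int = 3000,
) -> List[PromoterWindow]:
    """Promoter windows 0-``upstream_length`` bp upstream of each gene's TSS.

    The TSS is the annotated gene 5' end.  On '+' the window is
    ``[gene_start - L, gene_start)``; on '-' it is ``[gene_end, gene_end + L)``.
    Windows are clipped to ``[0, chrom_len)``; windows that become empty
    (TSS at a chromosome edge) are dropped with a logged warning.
    """
    windows: List[PromoterWindow] = []
    for row in annotation.itertuples(index=False):
        if row.chrom not in chrom_lengths:
            raise ValueError(f"gene {row.gene_id}: unknown chromosome {row.chrom!r}")
        clen = chrom_lengths[row.chrom]
        if not (0 <= row.start < row.end <= clen):
            raise ValueError(
                f"gene {row.gene_id}: span [{row.start},{row.end}) outside "
                f"chromosome {row.chrom} (length {clen})"
            )
        if row.strand == "+":
            start, end = max(0, row.start - upstream_length), row.start
        elif row.strand == "-":
            start, end = row.end, min(clen, row.end + upstream_length)
        else:
            raise ValueError(f"gene {row.gene_id}: bad strand {row.strand!r}")
        if start >= end:
            logger.warning(
                "gene %s: empty promoter window (TSS at chromosome edge), dropped",
                row.gene_id,
            )
            continue
        windows.append(PromoterWindow(row.gene_id, row.chrom, row.strand, start, end))
    return windows


def _match_mask(seq: str, pattern: MotifPattern) -> np.ndarray:
    """Boolean array of match starts: position-wise table lookup, vectorized."""
    L = len(pattern)
    n = len(seq)
    if n < L:
        return np.zeros(0, dtype=bool)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = np.ones(n - L + 1, dtype=bool)
    for k, base_set in enumerate(pattern.base_sets):
        tbl = np.zeros(256, dtype=bool)
        for b in base_set:  # genomic N stays False: matches nothing
            tbl[ord(b)] = True
        mask &= tbl[codes[k : k + n - L + 1]]
    return mask


def scan_motifs(
    genome: Genome,
    pattern: MotifPattern,
    regions: Optional[Sequence[PromoterWindow]] = None,
    strands: str = "both",
) -> List[MotifInstance]:
    """Find all pattern occurrences, genome-wide or inside promoter windows.

    Parameters
    ----------
    genome : mapping of name -> GenomeSequence
    pattern : MotifPattern
    regions : optional promoter windows; when given, only matches fully
        contained in at least one window are reported, and each instance's
        ``gene_ids`` collects every gene whose window overlaps it.
        Instances found in several overlapping windows are emitted once.
    strands : '+', '-' or 'both'
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    want = "+-" if strands == "both" else strands
    L = len(pattern)

    by_chrom_regions: Dict[str, List[PromoterWindow]] = {}
    if regions is not None:
        for w in regions:
            by_chrom_regions.setdefault(w.chrom, []).append(w)

    instances: Dict[tuple, MotifInstance] = {}
    for name, gs in genome.items():
        if regions is not None and name not in by_chrom_regions:
            continue
        seq = gs.seq
        n = len(seq)
        starts_by_strand: Dict[str, np.ndarray] = {}
        if "+" in want:
            starts_by_strand["+"] = np.nonzero(_match_mask(seq, pattern))[0]
        if "-" in want:
            rc = reverse_complement(seq)
            j = np.nonzero(_match_mask(rc, pattern))[0]
            starts_by_strand["-"] = np.sort(n - j - L)

        for strand, starts in starts_by_strand.items():
            if regions is not None:
                keep = np.zeros(len(starts), dtype=bool)
                for w in by_chrom_regions[name]:
                    keep |= (starts >= w.start) & (starts + L <= w.end)
                starts = starts[keep]
            for s in starts.tolist():
                sl = seq[s : s + L]
                matched = sl if strand == "+" else reverse_complement(sl)
                key = (name, s, s + L, strand)
                if key not in instances:
                    instances[key] = MotifInstance(name, s, s + L, strand, matched)

    if regions is not None:
        for inst in instances.values():
            for w in by_chrom_regions.get(inst.chrom, ()):
                if w.start < inst.end and inst.start < w.end:
                    inst.gene_ids.add(w.gene_id)

    return sorted(
        instances.values(), key=lambda i: (i.chrom, i.start, 0 if i.strand == "+" else 1)
    )


def write_instances_bed(
    instances: Iterable[MotifInstance],
    path: Union[str, Path],
    categories: Optional[Mapping[tuple, str]] = None,
) -> None:
    """Write instances as BED6; name = ``matched_seq;category`` when known."""
    with open(path, "w") as fh:
        for inst in instances:
            cat = categories.get(inst.key, "") if categories else ""
            name = f"{inst.matched_seq};{cat}" if cat else inst.matched_seq
            fh.write(
                f"{inst.chrom}\t{inst.start}\t{inst.end}\t{name}\t0\t{inst.strand}\n"
            )
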