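"""Genome sequences and FASTA input.

Sequences are plain uppercase strings over the {A, C, G, T, N} alphabet,
wrapped in a lightweight :class:`GenomeSequence` record.  All genomic
coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome/contig sequence.

    Attributes
    ----------
    name : str
        Chromosome identifier (FASTA record id).
    seq : str
        Uppercase sequence over {A, C, G, T, N}.
    """

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


Genome = Dict[str, GenomeSequence]


def load_genome(path: Union[str, Path]) -> Genome:
    """Read a FASTA file into an ordered ``{name: GenomeSequence}`` mapping.

    Lowercase input is accepted and uppercased.  Duplicate record names are
    rejected; characters outside {A,C,G,T,N} raise a parse error naming the
    record.
    """
    path = Path(path)
    genome: Genome = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"{path}: duplicate sequence name {record.id!r}")
        seq = str(record.seq).upper()
        try:
            genome[record.id] = GenomeSequence(record.id, seq)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: Genome, path: Union[str, Path], width: int = 60) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for gs in genome.values():
            fh.write(f">{gs.name}\n")
            for i in range(0, len(gs.seq), width):
                fh.write(gs.seq[i : i + width] + "\n")
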