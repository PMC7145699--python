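"""Consensus/conservation profiles over aligned protein sequences.

Used to summarize how conserved the DNA-reading residues of the R2 and R3
helix-turn-helix repeats are across a family alignment (a pre-made MSA is
an input; building alignments is out of scope).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

from Bio import AlignIO

GAP_CHARS = frozenset("-.")


def load_alignment(path: Union[str, Path]) -> List[str]:
    """Read an aligned FASTA into a list of equal-length sequences."""
    aln = AlignIO.read(str(path), "fasta")
    return [str(rec.seq).upper() for rec in aln]


def consensus_profile(
    msa: Sequence[str], columns: Sequence[int]
) -> Dict[int, Tuple[Dict[str, float], float]]:
    """Per-column residue frequencies for selected alignment columns.

    Parameters
    ----------
    msa : equal-length aligned sequences (gaps '-' or '.')
    columns : 0-based column indices

    Returns
    -------
    dict mapping column -> (frequencies over observed residues, gap fraction).
    Frequencies sum to 1 over non-gap residues; an all-gap column yields an
    empty frequency table and gap fraction 1.0.
    """
    if not msa:
        raise ValueError("empty alignment")
    length = len(msa[0])
    for i, seq in enumerate(msa):
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment: sequence {i} has length {len(seq)}, "
                f"expected {length}"
            )
    out: Dict[int, Tuple[Dict[str, float], float]] = {}
    n = len(msa)
    for col in columns:
        if not 0 <= col < length:
            raise ValueError(f"column {col} outside alignment of length {length}")
        residues = [seq[col].upper() for seq in msa]
        gaps = sum(r in GAP_CHARS for r in residues)
        observed = [r for r in residues if r not in GAP_CHARS]
        freqs: Dict[str, float] = {}
        for r in observed:
            freqs[r] = freqs.get(r, 0) + 1
        freqs = {r: c / len(observed) for r, c in freqs.items()} if observed else {}
        out[col] = (freqs, gaps / n)
    return out
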