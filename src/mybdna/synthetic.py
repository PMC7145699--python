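"""Synthetic inputs with recorded ground truth.

Every input the pipeline consumes can be generated here: a small genome
with planted AACNDN instances at recorded loci, TSS annotation,
strand-specific methylation calls with configurable per-position rates,
idealized protein-DNA interface fixtures, and noisy one-site thermograms.
All generators are deterministic under a seed, and each writes/returns a
truth record sufficient to score the downstream stage.

The module also carries a deliberately naive scanning/census oracle
(regex enumeration and plain loops, independent of the vectorized scanner)
used both by the generators to verify their own output and by the test
suite as the reference implementation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .isotherm import BindingParameters, Thermogram, TitrationProtocol, simulate_titration
from .methylome import MethylationCall, category_from_flags, CATEGORIES
from .motifs import IUPAC_CODES, MotifPattern, PromoterWindow, derive_promoters
from .sequences import Genome, GenomeSequence
from .structure import Atom, StructureModel
from . import chemistry as chem

# ---------------------------------------------------------------------------
# truth serialization


def save_truth(truth: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_truth(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# naive oracle (regex enumeration; independent of the table-driven scanner)


def _oracle_revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def oracle_scan(
    genome: Genome,
    pattern: Union[str, MotifPattern],
    regions: Optional[Sequence[PromoterWindow]] = None,
    strands: str = "both",
) -> Set[Tuple[str, int, int, str, str]]:
    """Brute-force enumeration of pattern matches via overlapping regex.

    Returns a set of (chrom, start, end, strand, matched_seq) tuples in
    genomic coordinates; the deliberately simple reference for
    :func:`mybdna.motifs.scan_motifs`.
    """
    pat = pattern if isinstance(pattern, MotifPattern) else MotifPattern(pattern)
    rx = re.compile("(?=(" + pat.regex() + "))")
    L = len(pat)
    want = "+-" if strands == "both" else strands
    hits: Set[Tuple[str, int, int, str, str]] = set()

    def scan_interval(name: str, seq: str, lo: int, hi: int) -> None:
        window = seq[lo:hi]
        if "+" in want:
            for m in rx.finditer(window):
                s = lo + m.start()
                hits.add((name, s, s + L, "+", m.group(1)))
        if "-" in want:
            rc = _oracle_revcomp(window)
            n = len(window)
            for m in rx.finditer(rc):
                j = m.start()
                s = lo + n - j - L
                hits.add((name, s, s + L, "-", m.group(1)))

    if regions is None:
        for name, gs in genome.items():
            scan_interval(name, gs.seq, 0, len(gs.seq))
    else:
        for w in regions:
            scan_interval(w.chrom, genome[w.chrom].seq, w.start, w.end)
    return hits


def oracle_census(
    genome: Genome,
    pattern: Union[str, MotifPattern],
    promoters: Sequence[PromoterWindow],
    calls: Iterable[MethylationCall],
    strands: str = "both",
) -> Dict[str, int]:
    """Census computed with plain loops and direct base-position lookups.

    Independent end-to-end reference for the scan -> attach -> tally
    pipeline: matches are enumerated by regex per window, per-gene credit
    by explicit interval overlap, methylation flags by membership of the
    (chrom, pos, strand, mod) tuple in a set.
    """
    hits = oracle_scan(genome, pattern, regions=promoters, strands=strands)
    call_set = {(c.chrom, c.pos, c.strand, c.mod_type) for c in calls}

    census: Dict[str, int] = {"total": len(hits)}
    for cat in CATEGORIES:
        census[cat] = 0
    genes: Set[str] = set()
    m5c = m6a1 = m6a2 = 0
    for chrom, start, end, strand, _seq in hits:
        for w in promoters:
            if w.chrom == chrom and w.start < end and start < w.end:
                genes.add(w.gene_id)

        def coord(k: int) -> int:
            return start + k - 1 if strand == "+" else end - k

        f5 = (chrom, coord(3), strand, "5mC") in call_set
        f61 = (chrom, coord(1), strand, "6mA") in call_set
        f62 = (chrom, coord(2), strand, "6mA") in call_set
        census[category_from_flags(f5, f61, f62)] += 1
        m5c += f5
        m6a1 += f61
        m6a2 += f62
    census["genes_with_instance"] = len(genes)
    census["any_methylated"] = census["total"] - census["unmethylated"]
    census["5mC_pos3"] = m5c
    census["6mA_pos1"] = m6a1
    census["6mA_pos2"] = m6a2
    return census


# ---------------------------------------------------------------------------
# genome + annotation generator

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeBundle:
    genome: Genome
    annotation: "object"  # pandas DataFrame (gene_id, chrom, start, end, strand)
    promoters: List[PromoterWindow]
    truth: dict


def gen_genome(
    n_chrom: int = 1,
    chrom_len: int = 100_000,
    n_genes: int = 50,
    n_planted_motifs: int = 200,
    gc: float = 0.36,
    seed: int = 0,
    pattern: str = "AACNDN",
    upstream_length: int = 3000,
) -> SyntheticGenomeBundle:
    """Generate a genome with i.i.d. background and planted motif instances.

    Background bases are i.i.d. with the given GC fraction (default 0.36,
    a plant-like composition).  Planted instances are written inside
    promoter windows at recorded loci, on random strands, with degenerate
    positions sampled uniformly from each code's base set; planted
    intervals never overlap each other.  Spurious background matches are
    permitted by design — downstream truth is established by the oracle.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0,1], got {gc}")
    pat = MotifPattern(pattern)
    L = len(pat)
    rng = np.random.default_rng(seed)

    import pandas as pd

    # background sequences
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chrom_arrays: Dict[str, np.ndarray] = {}
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        chrom_arrays[name] = _BASES[
            rng.choice(4, size=chrom_len, p=probs)
        ].copy()

    # gene slots: gene body mid-slot, random strand
    genes = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    for i, name in enumerate(chrom_arrays):
        k = per_chrom[i]
        if k == 0:
            continue
        slot = chrom_len // k
        if slot < 10:
            raise ValueError("chromosome too short for the requested gene count")
        gene_len = max(2, min(1000, slot // 2))
        for j in range(k):
            lo = j * slot
            body_start = lo + (slot - gene_len) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                {
                    "gene_id": f"g{len(genes) + 1:05d}",
                    "chrom": name,
                    "start": int(body_start),
                    "end": int(body_start + gene_len),
                    "strand": strand,
                }
            )
    annotation = pd.DataFrame(genes)
    chrom_lengths = {name: len(arr) for name, arr in chrom_arrays.items()}
    promoters = derive_promoters(annotation, chrom_lengths, upstream_length)
    if not promoters:
        raise ValueError("no promoter windows generated; cannot plant motifs")

    # plant motifs inside promoter windows, non-overlapping
    occupied: Dict[str, Set[int]] = {name: set() for name in chrom_arrays}
    planted: List[dict] = []
    attempts = 0
    max_attempts = 200 * max(1, n_planted_motifs)
    while len(planted) < n_planted_motifs:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place all motifs without overlap; "
                "reduce n_planted_motifs or enlarge the genome"
            )
        w = promoters[int(rng.integers(len(promoters)))]
        if w.end - w.start < L:
            continue
        start = int(rng.integers(w.start, w.end - L + 1))
        if any(p in occupied[w.chrom] for p in range(start, start + L)):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = "".join(
            sorted(s)[int(rng.integers(len(s)))] for s in pat.base_sets
        )
        genomic = seq if strand == "+" else _oracle_revcomp(seq)
        chrom_arrays[w.chrom][start : start + L] = np.frombuffer(
            genomic.encode(), dtype=np.uint8
        )
        occupied[w.chrom].update(range(start, start + L))
        planted.append(
            {
                "chrom": w.chrom,
                "start": start,
                "end": start + L,
                "strand": strand,
                "seq": seq,
            }
        )

    genome: Genome = {
        name: GenomeSequence(name, arr.tobytes().decode("ascii"))
        for name, arr in chrom_arrays.items()
    }
    # validate at write time: every planted sequence matches the pattern
    for p in planted:
        assert pat.matches(p["seq"]), "planted motif does not match pattern"

    truth = {
        "kind": "genome",
        "seed": int(seed),
        "pattern": pattern,
        "gc": gc,
        "upstream_length": upstream_length,
        "chrom_lengths": chrom_lengths,
        "genes": genes,
        "planted": planted,
    }
    return SyntheticGenomeBundle(genome, annotation, promoters, truth)


def write_genome_bundle(
    bundle: SyntheticGenomeBundle, out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Write FASTA + GFF3 + truth JSON; returns the paths."""
    from .sequences import write_genome

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    gff = out / "genes.gff3"
    truth = out / "genome.truth.json"
    write_genome(bundle.genome, fasta)
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.truth["genes"]:
            fh.write(
                f"{g['chrom']}\tmybdna\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )
    save_truth(bundle.truth, truth)
    return {"fasta": fasta, "gff3": gff, "truth": truth}


# ---------------------------------------------------------------------------
# methylome generator

_MOTIF_MOD_POSITIONS = ((3, "5mC"), (1, "6mA"), (2, "6mA"))


def gen_methylome(
    genome: Genome,
    truth: dict,
    p_5mC_pos3: float = 0.1,
    p_6mA_pos1: float = 0.005,
    p_6mA_pos2: float = 0.015,
    p_background: float = 0.005,
    seed: int = 0,
) -> Tuple[List[MethylationCall], List[MethylationCall], dict]:
    """Strand-correct methylation calls over a generated genome.

    Per planted motif the three flags (5mC at position 3, 6mA at positions
    1 and 2) are drawn independently with the stated probabilities and
    emitted as single-base calls on the motif strand.  Background calls
    are sprinkled at rate ``p_background`` per strand position, on
    chemically valid bases only (5mC on cytosines, 6mA on adenines of the
    respective strand).  The returned truth carries both the drawn flags
    and the *effective* flags recomputed from the final call set (a
    background call may land on a motif position).
    """
    for p in (p_5mC_pos3, p_6mA_pos1, p_6mA_pos2, p_background):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = (p_5mC_pos3, p_6mA_pos1, p_6mA_pos2)

    calls_5mc: Set[Tuple[str, int, str]] = set()
    calls_6ma: Set[Tuple[str, int, str]] = set()

    drawn_flags: List[dict] = []
    for motif in truth["planted"]:
        start, end, strand, chrom = (
            motif["start"], motif["end"], motif["strand"], motif["chrom"],
        )
        flags = {}
        for (k, mod), p in zip(_MOTIF_MOD_POSITIONS, probs):
            hit = bool(rng.random() < p)
            flags[f"{mod}_pos{k}"] = hit
            if hit:
                pos = start + k - 1 if strand == "+" else end - k
                (calls_5mc if mod == "5mC" else calls_6ma).add((chrom, pos, strand))
        drawn_flags.append(flags)

    # background on chemically valid bases: + strand base, - strand complement
    for name, gs in genome.items():
        arr = np.frombuffer(gs.seq.encode(), dtype=np.uint8)
        if p_background > 0:
            for mod, plus_base, minus_base, store in (
                ("5mC", ord("C"), ord("G"), calls_5mc),
                ("6mA", ord("A"), ord("T"), calls_6ma),
            ):
                for strand, base in (("+", plus_base), ("-", minus_base)):
                    idx = np.nonzero(arr == base)[0]
                    hit = idx[rng.random(len(idx)) < p_background]
                    store.update((name, int(i), strand) for i in hit)

    # effective flags from the final call set
    effective_flags: List[dict] = []
    for motif in truth["planted"]:
        start, end, strand, chrom = (
            motif["start"], motif["end"], motif["strand"], motif["chrom"],
        )
        flags = {}
        for k, mod in _MOTIF_MOD_POSITIONS:
            pos = start + k - 1 if strand == "+" else end - k
            store = calls_5mc if mod == "5mC" else calls_6ma
            flags[f"{mod}_pos{k}"] = (chrom, pos, strand) in store
        effective_flags.append(flags)

    truth = dict(truth)
    truth["methylome"] = {
        "seed": int(seed),
        "rates": {
            "p_5mC_pos3": p_5mC_pos3,
            "p_6mA_pos1": p_6mA_pos1,
            "p_6mA_pos2": p_6mA_pos2,
            "p_background": p_background,
        },
        "drawn_flags": drawn_flags,
        "effective_flags": effective_flags,
    }
    mk = lambda store, mod: [
        MethylationCall(c, p, s, mod, 1.0) for (c, p, s) in sorted(store)
    ]
    return mk(calls_5mc, "5mC"), mk(calls_6ma, "6mA"), truth


# ---------------------------------------------------------------------------
# structural fixture builder

#: idealized planar base-atom templates (x, y in Å, base plane z = 0),
#: standard reference-frame geometries; intra-base bond lengths are within
#: 0.1 Å of standard values (checked by the test suite).
BASE_TEMPLATES: Mapping[str, Tuple[Tuple[str, float, float], ...]] = {
    "A": (
        ("N9", -1.291, 4.498), ("C8", 0.024, 4.897), ("N7", 0.877, 3.902),
        ("C5", 0.071, 2.771), ("C6", 0.369, 1.398), ("N6", 1.611, 0.909),
        ("N1", -0.668, 0.532), ("C2", -1.912, 1.023), ("N3", -2.320, 2.290),
        ("C4", -1.267, 3.124),
    ),
    "G": (
        ("N9", -1.289, 4.551), ("C8", 0.023, 4.962), ("N7", 0.870, 3.969),
        ("C5", 0.071, 2.833), ("C6", 0.424, 1.460), ("O6", 1.554, 0.955),
        ("N1", -0.700, 0.641), ("C2", -1.999, 1.087), ("N2", -2.949, 0.139),
        ("N3", -2.342, 2.364), ("C4", -1.265, 3.177),
    ),
    "C": (
        ("N1", -1.285, 4.542), ("C2", -1.472, 3.158), ("O2", -2.628, 2.709),
        ("N3", -0.391, 2.344), ("C4", 0.837, 2.868), ("N4", 1.875, 2.027),
        ("C5", 1.056, 4.275), ("C6", -0.023, 5.068),
    ),
    "T": (
        ("N1", -1.284, 4.500), ("C2", -1.462, 3.135), ("O2", -2.562, 2.608),
        ("N3", -0.298, 2.407), ("C4", 0.994, 2.897), ("O4", 1.944, 2.119),
        ("C5", 1.106, 4.338), ("C7", 2.466, 4.961), ("C6", -0.024, 5.057),
    ),
}

_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def _element_of(atom_name: str) -> str:
    return atom_name[0]


@dataclass(frozen=True)
class Placement:
    """One requested probe-atom placement against a template base.

    ``base_key`` groups placements onto the same base copy.  ``kind`` is
    ``direct`` (H-bond geometry), ``apolar`` or ``water`` (a single-water
    bridge: the water sits ``water_distance`` from the DNA target atom and
    ``distance`` from the probe atom).  ``direction`` optionally overrides
    the default in-plane direction (exocyclic bisector at the target).
    """

    base: str  # A | C | G | T
    base_key: str
    target_atom: str
    probe_resname: str
    probe_atom: str
    distance: float
    kind: str = "direct"
    water_distance: float = 2.8
    direction: Optional[Tuple[float, float, float]] = None


def _base_atoms(base: str) -> Dict[str, np.ndarray]:
    return {
        name: np.array([x, y, 0.0])
        for name, x, y in BASE_TEMPLATES[base]
    }


def _default_direction(atoms: Dict[str, np.ndarray], target: str) -> np.ndarray:
    """Outward in-plane direction at the target atom.

    Exocyclic bisector away from the two nearest covalent neighbours —
    falls back to centroid->target when the target has one neighbour.
    """
    t = atoms[target]
    others = sorted(
        (np.linalg.norm(p - t), name) for name, p in atoms.items() if name != target
    )
    neighbours = [atoms[name] for d, name in others if d < 1.8][:2]
    if len(neighbours) == 2:
        u = sum(
            (t - nb) / np.linalg.norm(t - nb) for nb in neighbours
        )
    else:
        centroid = np.mean(list(atoms.values()), axis=0)
        u = t - centroid
    norm = np.linalg.norm(u)
    if norm < 1e-9:  # pragma: no cover - degenerate geometry
        raise ValueError(f"cannot derive a direction at {target}")
    return u / norm


def equidistant_direction(
    base: str, atom_a: str, atom_b: str, distance: float
) -> Tuple[str, Tuple[float, float, float]]:
    """Helper for bidentate geometries: the in-plane point at ``distance``
    from both named atoms (e.g. Lys NZ read of guanine O6 *and* N7).

    Returns (target_atom, direction) suitable for a :class:`Placement`
    with that target: probe = target + distance * direction.
    """
    atoms = _base_atoms(base)
    a, b = atoms[atom_a], atoms[atom_b]
    m = (a + b) / 2.0
    half = np.linalg.norm(b - a) / 2.0
    if distance <= half:
        raise ValueError("distance smaller than half the atom separation")
    offset = float(np.sqrt(distance**2 - half**2))
    axis = (b - a) / np.linalg.norm(b - a)
    perp = np.array([axis[1], -axis[0], 0.0])
    centroid = np.mean(list(atoms.values()), axis=0)
    if np.dot(perp, m - centroid) < 0:
        perp = -perp
    point = m + offset * perp
    u = (point - a) / np.linalg.norm(point - a)
    return atom_a, (float(u[0]), float(u[1]), float(u[2]))


def build_fixture(
    placements: Sequence[Placement],
    spacing: float = 30.0,
    verify: bool = True,
    d_hb: float = 3.5,
    d_ap: float = 4.5,
) -> Tuple[StructureModel, dict]:
    """Assemble an idealized interface fixture from placement requests.

    Each distinct ``base_key`` gets one copy of its base template, offset
    ``spacing`` Å from the previous copy so that groups cannot interact.
    Probe residues are built as single named atoms placed at the exact
    requested distance from the target atom.  The returned truth records
    the intended contact list; with ``verify=True`` the builder
    brute-forces all protein-DNA pairs and raises if the geometry produced
    any contact beyond the planted ones.
    """
    groups: Dict[str, Tuple[str, int]] = {}
    order: List[str] = []
    for p in placements:
        if p.base_key not in groups:
            if p.base not in BASE_TEMPLATES:
                raise ValueError(f"unknown base template {p.base!r}")
            groups[p.base_key] = (p.base, len(order))
            order.append(p.base_key)
        elif groups[p.base_key][0] != p.base:
            raise ValueError(f"base_key {p.base_key!r} reused with another base")

    atoms: List[Atom] = []
    planted: List[dict] = []
    probe_num = 200
    water_num = 900

    base_coords: Dict[str, Dict[str, np.ndarray]] = {}
    for key in order:
        base, idx = groups[key]
        offset = np.array([idx * spacing, 0.0, 0.0])
        coords = {n: p + offset for n, p in _base_atoms(base).items()}
        base_coords[key] = coords
        resnum = idx + 1
        for name, pos in coords.items():
            atoms.append(
                Atom("D", resnum, _RESNAME[base], name, _element_of(name),
                     tuple(round(v, 3) for v in pos))
            )

    for p in placements:
        base, idx = groups[p.base_key]
        coords = base_coords[p.base_key]
        if p.target_atom not in coords:
            raise ValueError(f"{p.base} template has no atom {p.target_atom!r}")
        target = coords[p.target_atom]
        if p.direction is not None:
            u = np.asarray(p.direction, dtype=float)
            u = u / np.linalg.norm(u)
        else:
            local = {n: c - np.array([idx * spacing, 0.0, 0.0]) for n, c in coords.items()}
            u = _default_direction(local, p.target_atom)
        dna_resnum = idx + 1
        dna_resname = _RESNAME[base]
        if p.kind == "water":
            wpos = target + p.water_distance * u
            ppos = target + (p.water_distance + p.distance) * u
            water_num += 1
            probe_num += 1
            atoms.append(Atom("W", water_num, "HOH", "O", "O",
                              tuple(round(v, 3) for v in wpos)))
            atoms.append(Atom("P", probe_num, p.probe_resname, p.probe_atom,
                              _element_of(p.probe_atom),
                              tuple(round(v, 3) for v in ppos)))
            planted.append(
                {
                    "kind": "water-mediated",
                    "protein": f"P/{p.probe_resname}{probe_num}/{p.probe_atom}",
                    "dna": f"D/{dna_resname}{dna_resnum}/{p.target_atom}",
                    "water": f"W/HOH{water_num}/O",
                    "distance": p.water_distance,
                }
            )
        else:
            ppos = target + p.distance * u
            probe_num += 1
            atoms.append(Atom("P", probe_num, p.probe_resname, p.probe_atom,
                              _element_of(p.probe_atom),
                              tuple(round(v, 3) for v in ppos)))
            kind = "direct-hbond" if p.kind == "direct" else "apolar-proximity"
            planted.append(
                {
                    "kind": kind,
                    "protein": f"P/{p.probe_resname}{probe_num}/{p.probe_atom}",
                    "dna": f"D/{dna_resname}{dna_resnum}/{p.target_atom}",
                    "water": None,
                    "distance": p.distance,
                }
            )
            # bidentate geometry: a direction chosen equidistant from a second
            # polar atom plants a second record for the same probe
            if p.direction is not None and p.kind == "direct":
                for name, pos in coords.items():
                    if name == p.target_atom:
                        continue
                    d = float(np.linalg.norm(ppos - pos))
                    roles = chem.dna_polar_roles(dna_resname, name)
                    if roles and abs(d - p.distance) < 5e-3:
                        planted.append(
                            {
                                "kind": kind,
                                "protein": f"P/{p.probe_resname}{probe_num}/{p.probe_atom}",
                                "dna": f"D/{dna_resname}{dna_resnum}/{name}",
                                "water": None,
                                "distance": round(d, 3),
                            }
                        )

    model = StructureModel(atoms)
    truth = {
        "kind": "fixture",
        "planted_contacts": planted,
        "n_bases": len(order),
        "n_probes": probe_num - 200,
    }
    if verify:
        _verify_fixture(model, truth, d_hb=d_hb, d_ap=d_ap)
    return model, truth


def _verify_fixture(
    model: StructureModel, truth: dict, d_hb: float, d_ap: float
) -> None:
    """Brute-force every protein/DNA atom pair; the realized contact set
    must equal the planted one (rounded distances aside)."""
    planted = {
        (c["protein"], c["dna"], c["kind"]) for c in truth["planted_contacts"]
    }
    realized: Set[Tuple[str, str, str]] = set()
    protein = model.protein_atoms
    nucleic = model.nucleic_atoms
    waters = model.water_atoms
    for p in protein:
        proles = chem.protein_polar_roles(p.resname, p.name)
        papolar = chem.protein_is_apolar(p.resname, p.name)
        for d in nucleic:
            dist = float(np.linalg.norm(p.xyz() - d.xyz()))
            droles = chem.dna_polar_roles(d.resname, d.name)
            if proles and droles and dist <= d_hb:
                if (chem.DONOR in proles and chem.ACCEPTOR in droles) or (
                    chem.ACCEPTOR in proles and chem.DONOR in droles
                ):
                    realized.add((p.id, d.id, "direct-hbond"))
            if papolar and dist <= d_ap and chem.dna_is_base_carbon(d.resname, d.name):
                realized.add((p.id, d.id, "apolar-proximity"))
    for w in waters:
        near_p = [p for p in protein
                  if chem.protein_polar_roles(p.resname, p.name)
                  and np.linalg.norm(w.xyz() - p.xyz()) <= d_hb]
        near_d = [d for d in nucleic
                  if chem.dna_polar_roles(d.resname, d.name)
                  and np.linalg.norm(w.xyz() - d.xyz()) <= d_hb]
        for p in near_p:
            for d in near_d:
                realized.add((p.id, d.id, "water-mediated"))
    if realized != planted:
        extra = realized - planted
        missing = planted - realized
        raise ValueError(
            "fixture geometry does not realize the requested contact list: "
            f"extra={sorted(extra)}, missing={sorted(missing)}"
        )


def wer_interface_placements() -> List[Placement]:
    """The composite WER-like interface fixture.

    Mirrors the five printed readout geometries of the complex — Asn
    ND2<->adenine N7 at 2.9 Å and Asn OD1<->adenine N6 at 3.0 Å (first
    adenine), a bidentate Lys NZ read of guanine O6/N7 at 2.9 Å each, Leu
    CD2 packing against cytosine C5 at 3.7 Å, and Lys NZ<->guanine O6 at
    2.7 Å — plus the second adenine's N6<->Asn OD1 bond at 3.0 Å, so both
    adenines of the AAC core donate through N6.
    """
    target, direction = equidistant_direction("G", "O6", "N7", 2.9)
    return [
        Placement("A", "A10", "N7", "ASN", "ND2", 2.9),
        Placement("A", "A10", "N6", "ASN", "OD1", 3.0),
        Placement("A", "A11", "N6", "ASN", "OD1", 3.0),
        Placement("G", "G11c", target, "LYS", "NZ", 2.9, direction=direction),
        Placement("C", "C12", "C5", "LEU", "CD2", 3.7, kind="apolar"),
        Placement("G", "G14", "O6", "LYS", "NZ", 2.7),
    ]


# ---------------------------------------------------------------------------
# thermogram generator


def gen_thermograms(
    param_grid: Sequence[BindingParameters],
    protocol: TitrationProtocol = TitrationProtocol(),
    noise_sd: float = 0.0,
    reps: int = 1,
    seed: int = 0,
) -> Tuple[List[Tuple[BindingParameters, int, Thermogram]], dict]:
    """Simulate ``reps`` noisy thermograms per parameter set.

    Delegates to :func:`mybdna.isotherm.simulate_titration`; per-replicate
    seeds are spawned deterministically from ``seed``.
    """
    out: List[Tuple[BindingParameters, int, Thermogram]] = []
    truth_sets = []
    rng = np.random.default_rng(seed)
    for params in param_grid:
        rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
        for rep in range(reps):
            tg = simulate_titration(
                params, protocol, noise_sd=noise_sd, seed=int(rep_seeds[rep])
            )
            out.append((params, rep, tg))
        truth_sets.append(
            {
                "n": params.n,
                "kd_uM": params.kd,
                "dh_cal_mol": params.dh,
                "q0_ucal": params.q0,
                "rep_seeds": [int(s) for s in rep_seeds],
            }
        )
    truth = {
        "kind": "thermograms",
        "seed": int(seed),
        "noise_sd_ucal": noise_sd,
        "reps": reps,
        "parameter_sets": truth_sets,
    }
    return out, truth
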