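"""Protein-DNA contact analysis and 5mC/6mA sensitivity prediction.

The R2R3-MYB domain reads its element through the third helix of each
helix-turn-helix repeat, inserted into the DNA major groove.  Given atomic
coordinates of a complex, this module enumerates

* direct hydrogen bonds (heavy-atom donor/acceptor pairs within ``d_hb``;
  no angle criterion, since crystal models carry no hydrogens),
* apolar proximities (protein apolar carbon/sulfur near a DNA base carbon
  within ``d_ap``), and
* water-mediated bridges (one ordered water within ``d_hb`` of both a
  protein polar atom and a DNA polar atom),

classifies each contact as base-specific versus backbone (phosphate/sugar),
and applies two methylation-sensitivity rules:

* **5mC steric rule** — a cytosine read through its major-groove edge is
  flagged when an idealized 5-methyl carbon (placed in the base plane along
  the C4->C5 exocyclic direction) would clash with a protein atom, or when
  a protein apolar atom already packs against ring carbon C5;
* **6mA donor-occlusion rule** — an adenine is flagged when its exocyclic
  N6 amine donates a direct base hydrogen bond to the protein; N6
  methylation compromises that donation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import chemistry as chem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    pos: Tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def id(self) -> str:
        return f"{self.chain}/{self.resname}{self.resnum}/{self.name}"

    @property
    def residue_id(self) -> Tuple[str, int, str]:
        return (self.chain, self.resnum, self.resname)

    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


def classify_residue(resname: str) -> str:
    if resname in chem.AMINO_ACIDS:
        return "protein"
    if resname in chem.NUCLEOTIDES:
        return "nucleic"
    if resname in chem.WATERS:
        return "water"
    return "other"


@dataclass
class StructureModel:
    """Atoms of a complex, grouped by chemical class."""

    atoms: List[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if not all(math.isfinite(v) for v in a.pos):
                raise ValueError(f"non-finite coordinates for atom {a.id}")
            key = (a.chain, a.resnum, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom after altloc resolution: {a.id}")
            seen.add(key)

    def subset(self, kind: str) -> List[Atom]:
        return [a for a in self.atoms if classify_residue(a.resname) == kind]

    @property
    def protein_atoms(self) -> List[Atom]:
        return self.subset("protein")

    @property
    def nucleic_atoms(self) -> List[Atom]:
        return self.subset("nucleic")

    @property
    def water_atoms(self) -> List[Atom]:
        return self.subset("water")

    def residue_atoms(self, residue_id: Tuple[str, int, str]) -> Dict[str, Atom]:
        return {a.name: a for a in self.atoms if a.residue_id == residue_id}


def parse_structure(path: Union[str, Path]) -> StructureModel:
    """Read ATOM/HETATM records from a PDB-format file via gemmi.

    Only the first altloc of each atom is kept; chains are classified by
    residue name.  A model without any nucleic chain is accepted with a
    warning (contacts are then trivially absent).
    """
    import gemmi

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed PDB file: {exc}") from exc
    st.remove_alternative_conformations()  # keep first altloc
    atoms: List[Atom] = []
    for model in st:
        for ch in model:
            for res in ch:
                for at in res:
                    atoms.append(
                        Atom(
                            chain=ch.name,
                            resnum=res.seqid.num,
                            resname=res.name.strip(),
                            name=at.name,
                            element=at.element.name,
                            pos=(at.pos.x, at.pos.y, at.pos.z),
                            occupancy=at.occ,
                        )
                    )
        break  # first model only
    model_obj = StructureModel(atoms)
    if not model_obj.nucleic_atoms:
        logger.warning("%s: no nucleic chain found; contact lists will be empty", path)
    return model_obj


def write_structure(model: StructureModel, path: Union[str, Path]) -> None:
    """Write a model as PDB (coordinates round-trip at PDB's 0.001 Å grid)."""
    import gemmi

    # gemmi containers copy on add: assemble bottom-up
    by_chain: Dict[str, Dict[Tuple[int, str], List[Atom]]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain, {}).setdefault((a.resnum, a.resname), []).append(a)

    st = gemmi.Structure()
    st.name = "mybdna"
    gm = gemmi.Model("1")
    for chain_name, residues in by_chain.items():
        ch = gemmi.Chain(chain_name)
        for (resnum, resname), atoms in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            if resname in chem.WATERS:
                res.het_flag = "H"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.pos)
                at.occ = a.occupancy
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class ContactRecord:
    """One protein-DNA contact (direct, water-mediated, or apolar)."""

    protein_atom: Atom
    dna_atom: Atom
    distance: float
    kind: str  # direct-hbond | water-mediated | apolar-proximity
    dna_class: str  # base | phosphate | sugar
    bridging_water: Optional[Atom] = None
    protein_water_distance: Optional[float] = None

    @property
    def signature(self) -> tuple:
        water = self.bridging_water.id if self.bridging_water else None
        return (self.protein_atom.id, self.dna_atom.id, self.kind, water)


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.xyz() - b.xyz()))


def _warn_unknown_residues(atoms: Iterable[Atom]) -> None:
    unknown = {a.resname for a in atoms if classify_residue(a.resname) == "other"}
    for resname in sorted(unknown):
        logger.warning("unknown residue %s skipped by contact chemistry", resname)


def find_contacts(
    model: StructureModel, d_hb: float = 3.5, d_ap: float = 4.5
) -> List[ContactRecord]:
    """Direct H-bonds and apolar proximities between protein and DNA.

    An H-bond needs donor/acceptor complementarity and a heavy-atom
    distance <= ``d_hb``; an apolar proximity needs a protein apolar
    carbon/sulfur within ``d_ap`` of a DNA base carbon.
    """
    _warn_unknown_residues(model.atoms)
    protein = model.protein_atoms
    nucleic = model.nucleic_atoms
    records: List[ContactRecord] = []
    if not protein or not nucleic:
        return records

    from scipy.spatial import cKDTree

    dna_xyz = np.array([a.xyz() for a in nucleic])
    tree = cKDTree(dna_xyz)
    rmax = max(d_hb, d_ap)
    for p in protein:
        p_roles = chem.protein_polar_roles(p.resname, p.name)
        p_apolar = chem.protein_is_apolar(p.resname, p.name)
        if p_roles is None and not p_apolar:
            continue
        for j in tree.query_ball_point(p.xyz(), rmax):
            d = nucleic[j]
            dist = _dist(p, d)
            cls = chem.dna_atom_class(d.name)
            if p_roles is not None and dist <= d_hb:
                d_roles = chem.dna_polar_roles(d.resname, d.name)
                if d_roles is not None and (
                    (chem.DONOR in p_roles and chem.ACCEPTOR in d_roles)
                    or (chem.ACCEPTOR in p_roles and chem.DONOR in d_roles)
                ):
                    records.append(
                        ContactRecord(p, d, round(dist, 4), "direct-hbond", cls)
                    )
            if (
                p_apolar
                and dist <= d_ap
                and chem.dna_is_base_carbon(d.resname, d.name)
            ):
                records.append(
                    ContactRecord(p, d, round(dist, 4), "apolar-proximity", "base")
                )
    records.sort(key=lambda r: (r.dna_atom.id, r.protein_atom.id, r.kind))
    return records


def find_water_bridges(model: StructureModel, d_hb: float = 3.5) -> List[ContactRecord]:
    """Single-water bridges: water O within ``d_hb`` of a protein polar atom
    and a DNA polar atom, one record per (protein atom, water, DNA atom)
    triple.  Complementarity is not enforced through the water (water is
    both donor and acceptor)."""
    waters = [a for a in model.water_atoms if a.element.upper() == "O"]
    protein_polar = [
        a
        for a in model.protein_atoms
        if chem.protein_polar_roles(a.resname, a.name) is not None
    ]
    dna_polar = [
        a
        for a in model.nucleic_atoms
        if chem.dna_polar_roles(a.resname, a.name) is not None
    ]
    records: List[ContactRecord] = []
    for w in waters:
        near_p = [(p, _dist(w, p)) for p in protein_polar]
        near_p = [(p, d) for p, d in near_p if d <= d_hb]
        if not near_p:
            continue
        near_d = [(d, _dist(w, d)) for d in dna_polar]
        near_d = [(d, x) for d, x in near_d if x <= d_hb]
        for p, pd in near_p:
            for d, dd in near_d:
                records.append(
                    ContactRecord(
                        p,
                        d,
                        round(dd, 4),
                        "water-mediated",
                        chem.dna_atom_class(d.name),
                        bridging_water=w,
                        protein_water_distance=round(pd, 4),
                    )
                )
    records.sort(key=lambda r: (r.dna_atom.id, r.protein_atom.id, r.signature))
    return records


#: default helix ranges of the WER R2/R3 reading helices (residue numbers)
DEFAULT_HELICES: Mapping[str, Tuple[int, int]] = {"H3": (54, 65), "H6": (105, 116)}


def readout_map(
    contacts: Sequence[ContactRecord],
    helices: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> Dict[str, object]:
    """Per-DNA-residue contact summary.

    A DNA residue with at least one base-class contact is labeled
    ``base-specific``; residues touched only through phosphate/sugar atoms
    are ``backbone-only``.  When helix ranges are supplied (defaults: the
    two DNA-reading helices H3 and H6), the protein residues making
    base-specific contacts are also listed per helix.
    """
    if helices is None:
        helices = DEFAULT_HELICES
    per_residue: Dict[Tuple[str, int, str], Dict[str, object]] = {}
    for c in contacts:
        entry = per_residue.setdefault(
            c.dna_atom.residue_id, {"contacts": [], "base_specific": False}
        )
        entry["contacts"].append(c)
        if c.dna_class == "base":
            entry["base_specific"] = True
    residues = {
        "/".join([rid[0], f"{rid[2]}{rid[1]}"]): {
            "label": "base-specific" if e["base_specific"] else "backbone-only",
            "n_contacts": len(e["contacts"]),
            "kinds": sorted({c.kind for c in e["contacts"]}),
        }
        for rid, e in per_residue.items()
    }
    helix_readout: Dict[str, List[str]] = {}
    for name, (lo, hi) in helices.items():
        residues_in_helix = sorted(
            {
                f"{c.protein_atom.resname}{c.protein_atom.resnum}"
                for c in contacts
                if c.dna_class == "base" and lo <= c.protein_atom.resnum <= hi
            }
        )
        helix_readout[name] = residues_in_helix
    return {"dna_residues": residues, "helices": helix_readout}


@dataclass(frozen=True)
class MethylSensitivitySite:
    """A DNA base predicted to be methylation-sensitive for binding."""

    dna_residue: Tuple[str, int, str]
    modification: str  # 5mC | 6mA
    mechanism: str  # steric-clash | donor-occlusion
    evidence: Tuple[str, ...]


def virtual_methyl_position(c4: np.ndarray, c5: np.ndarray, bond: float = 1.50) -> np.ndarray:
    """Idealized 5-methyl carbon: in the base plane, along C4->C5, at
    ``bond`` Å from C5 (planar placement, no rotamer search)."""
    u = c5 - c4
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("degenerate C4/C5 coordinates")
    return c5 + bond * u / norm


def predict_methyl_sensitivity(
    model: StructureModel,
    contacts: Sequence[ContactRecord],
    clash_tol: float = 0.4,
    methyl_bond: float = 1.50,
) -> List[MethylSensitivitySite]:
    """Apply the 5mC steric rule and the 6mA donor-occlusion rule.

    5mC: for each cytosine with >= 1 base contact, place a virtual methyl
    carbon at C5 (see :func:`virtual_methyl_position`) and flag a steric
    clash if any protein atom comes within ``vdW_C + vdW_other -
    clash_tol`` of it, or if an apolar proximity to C5 at <= 4.0 Å already
    exists.  6mA: flag each adenine whose N6 donates >= 1 direct base
    H-bond.
    """
    sites: List[MethylSensitivitySite] = []

    base_contacted = {}
    for c in contacts:
        if c.dna_class == "base":
            base_contacted.setdefault(c.dna_atom.residue_id, []).append(c)

    # (a) 5mC steric rule on read-out cytosines
    cyt_residues = sorted(
        rid
        for rid in base_contacted
        if chem._base_letter(rid[2]) == "C"
    )
    protein = model.protein_atoms
    for rid in cyt_residues:
        atoms = model.residue_atoms(rid)
        evidence: List[str] = []
        if "C4" in atoms and "C5" in atoms:
            vm = virtual_methyl_position(
                atoms["C4"].xyz(), atoms["C5"].xyz(), methyl_bond
            )
            for p in protein:
                cutoff = (
                    chem.vdw_radius("C") + chem.vdw_radius(p.element) - clash_tol
                )
                d = float(np.linalg.norm(vm - p.xyz()))
                if d < cutoff:
                    evidence.append(f"virtual-5-methyl clash with {p.id} at {d:.2f} Å")
        for c in base_contacted[rid]:
            if (
                c.kind == "apolar-proximity"
                and c.dna_atom.name == "C5"
                and c.distance <= 4.0
            ):
                evidence.append(
                    f"apolar packing {c.protein_atom.id}-C5 at {c.distance:.2f} Å"
                )
        if evidence:
            sites.append(
                MethylSensitivitySite(rid, "5mC", "steric-clash", tuple(evidence))
            )

    # (b) 6mA donor-occlusion rule on adenines donating through N6
    ade_n6: Dict[Tuple[str, int, str], List[str]] = {}
    for c in contacts:
        if (
            c.kind == "direct-hbond"
            and c.dna_class == "base"
            and chem._base_letter(c.dna_atom.resname) == "A"
            and c.dna_atom.name == "N6"
        ):
            ade_n6.setdefault(c.dna_atom.residue_id, []).append(
                f"N6 H-bond to {c.protein_atom.id} at {c.distance:.2f} Å"
            )
    for rid in sorted(ade_n6):
        sites.append(
            MethylSensitivitySite(rid, "6mA", "donor-occlusion", tuple(ade_n6[rid]))
        )
    return sites


def contacts_to_table(contacts: Sequence[ContactRecord]):
    """Contacts as a pandas DataFrame (one row per record), for TSV export."""
    import pandas as pd

    rows = []
    for c in contacts:
        rows.append(
            {
                "protein_chain": c.protein_atom.chain,
                "protein_residue": f"{c.protein_atom.resname}{c.protein_atom.resnum}",
                "protein_atom": c.protein_atom.name,
                "dna_chain": c.dna_atom.chain,
                "dna_residue": f"{c.dna_atom.resname}{c.dna_atom.resnum}",
                "dna_atom": c.dna_atom.name,
                "distance_A": c.distance,
                "kind": c.kind,
                "dna_class": c.dna_class,
                "bridging_water": c.bridging_water.id if c.bridging_water else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_chain", "protein_residue", "protein_atom",
            "dna_chain", "dna_residue", "dna_atom",
            "distance_A", "kind", "dna_class", "bridging_water",
        ],
    )
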