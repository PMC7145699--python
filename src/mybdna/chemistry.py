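"""Atom-role chemistry tables for protein-DNA contact detection.

Roles are assigned per (residue name, atom name):

* ``donor`` / ``acceptor`` — hydrogen-bond capability of the heavy atom
  (no hydrogens are present in crystal models, so donor/acceptor identity
  is taken from standard chemistry, and an H-bond is scored by distance
  plus donor/acceptor complementarity only);
* ``apolar`` — aliphatic/aromatic carbon or thioether/thiol sulfur,
  eligible for apolar-proximity contacts;
* DNA atoms additionally carry a backbone/sugar/base class.

His ND1/NE2 are treated as donor+acceptor (protonation unresolved in
crystal structures).  Cys SG and Met SD are scored as apolar sulfurs, not
as H-bond partners.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Optional, Tuple

DONOR = "donor"
ACCEPTOR = "acceptor"

#: van der Waals radii (Å) for the steric screen
VDW_RADII: Dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
VDW_DEFAULT = 1.70

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
NUCLEOTIDES = frozenset("DA DC DG DT DU A C G T U".split())
WATERS = frozenset({"HOH", "WAT", "DOD"})

# --- protein side-chain polar roles -------------------------------------------------
_PROTEIN_POLAR: Dict[Tuple[str, str], FrozenSet[str]] = {}


def _p(res: str, atom: str, *roles: str) -> None:
    _PROTEIN_POLAR[(res, atom)] = frozenset(roles)


_p("ARG", "NE", DONOR)
_p("ARG", "NH1", DONOR)
_p("ARG", "NH2", DONOR)
_p("ASN", "ND2", DONOR)
_p("ASN", "OD1", ACCEPTOR)
_p("GLN", "NE2", DONOR)
_p("GLN", "OE1", ACCEPTOR)
_p("ASP", "OD1", ACCEPTOR)
_p("ASP", "OD2", ACCEPTOR)
_p("GLU", "OE1", ACCEPTOR)
_p("GLU", "OE2", ACCEPTOR)
_p("HIS", "ND1", DONOR, ACCEPTOR)
_p("HIS", "NE2", DONOR, ACCEPTOR)
_p("LYS", "NZ", DONOR)
_p("SER", "OG", DONOR, ACCEPTOR)
_p("THR", "OG1", DONOR, ACCEPTOR)
_p("TYR", "OH", DONOR, ACCEPTOR)
_p("TRP", "NE1", DONOR)

# --- protein apolar carbons/sulfurs -------------------------------------------------
_PROTEIN_APOLAR: Dict[str, FrozenSet[str]] = {
    "ALA": frozenset({"CB"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "MET": frozenset({"CB", "CG", "SD", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "PRO": frozenset({"CB", "CG", "CD"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "LYS": frozenset({"CB", "CG", "CD", "CE"}),
    "ARG": frozenset({"CB", "CG", "CD"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLN": frozenset({"CB", "CG"}),
    "ASP": frozenset({"CB"}),
    "ASN": frozenset({"CB"}),
    "HIS": frozenset({"CB"}),
    "CYS": frozenset({"CB", "SG"}),
    "SER": frozenset({"CB"}),
    "THR": frozenset({"CB", "CG2"}),
    "GLY": frozenset(),
}


def protein_polar_roles(resname: str, atom: str) -> Optional[FrozenSet[str]]:
    """Donor/acceptor roles of a protein atom, or None if apolar/unknown."""
    if atom == "N" and resname != "PRO":  # backbone amide
        return frozenset({DONOR})
    if atom in ("O", "OXT"):  # backbone carbonyl / terminal carboxylate
        return frozenset({ACCEPTOR})
    return _PROTEIN_POLAR.get((resname, atom))


def protein_is_apolar(resname: str, atom: str) -> bool:
    return atom in _PROTEIN_APOLAR.get(resname, frozenset())


# --- DNA ----------------------------------------------------------------------------
_PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"})
_SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'", "O5'",
                          "O2'"})


def dna_atom_class(atom: str) -> str:
    """phosphate | sugar | base classification of a nucleotide atom."""
    if atom in _PHOSPHATE_ATOMS:
        return "phosphate"
    if atom in _SUGAR_ATOMS:
        return "sugar"
    return "base"


def _base_letter(resname: str) -> str:
    return resname[-1]  # DA -> A, DT -> T, A -> A ...


_BASE_POLAR: Dict[Tuple[str, str], FrozenSet[str]] = {
    # adenine
    ("A", "N6"): frozenset({DONOR}),
    ("A", "N7"): frozenset({ACCEPTOR}),
    ("A", "N1"): frozenset({ACCEPTOR}),
    ("A", "N3"): frozenset({ACCEPTOR}),
    # guanine
    ("G", "O6"): frozenset({ACCEPTOR}),
    ("G", "N7"): frozenset({ACCEPTOR}),
    ("G", "N1"): frozenset({DONOR}),
    ("G", "N2"): frozenset({DONOR}),
    ("G", "N3"): frozenset({ACCEPTOR}),
    # cytosine
    ("C", "N4"): frozenset({DONOR}),
    ("C", "N3"): frozenset({ACCEPTOR}),
    ("C", "O2"): frozenset({ACCEPTOR}),
    # thymine / uracil
    ("T", "N3"): frozenset({DONOR}),
    ("T", "O4"): frozenset({ACCEPTOR}),
    ("T", "O2"): frozenset({ACCEPTOR}),
    ("U", "N3"): frozenset({DONOR}),
    ("U", "O4"): frozenset({ACCEPTOR}),
    ("U", "O2"): frozenset({ACCEPTOR}),
}

_BASE_CARBONS: Dict[str, FrozenSet[str]] = {
    "A": frozenset({"C2", "C4", "C5", "C6", "C8"}),
    "G": frozenset({"C2", "C4", "C5", "C6", "C8"}),
    "C": frozenset({"C2", "C4", "C5", "C6"}),
    "T": frozenset({"C2", "C4", "C5", "C6", "C7", "C5M"}),
    "U": frozenset({"C2", "C4", "C5", "C6"}),
}


def dna_polar_roles(resname: str, atom: str) -> Optional[FrozenSet[str]]:
    """Donor/acceptor roles of a DNA atom (base or backbone oxygens)."""
    cls = dna_atom_class(atom)
    if cls == "base":
        return _BASE_POLAR.get((_base_letter(resname), atom))
    if atom.startswith("O"):  # phosphate / sugar oxygens accept H-bonds
        return frozenset({ACCEPTOR})
    return None


def dna_is_base_carbon(resname: str, atom: str) -> bool:
    return atom in _BASE_CARBONS.get(_base_letter(resname), frozenset())


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)
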