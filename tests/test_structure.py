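"""Contact detection, water bridges, readout map, methylation rules."""

import itertools

import numpy as np
import pytest

from mybdna import (
    Atom,
    StructureModel,
    find_contacts,
    find_water_bridges,
    parse_structure,
    predict_methyl_sensitivity,
    readout_map,
    write_structure,
)
from mybdna import chemistry as chem
from mybdna.structure import virtual_methyl_position
from mybdna.synthetic import BASE_TEMPLATES, Placement, build_fixture


def _base(base, key=1, offset=(0.0, 0.0, 0.0)):
    resname = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}[base]
    return [
        Atom("D", key, resname, name, name[0],
             (x + offset[0], y + offset[1], offset[2]))
        for name, x, y in BASE_TEMPLATES[base]
    ]


def _atom_xy(base, name):
    return next((x, y) for n, x, y in BASE_TEMPLATES[base] if n == name)


def _probe(resname, atom, pos, resnum=500, chain="P"):
    return Atom(chain, resnum, resname, atom, atom[0], tuple(pos))


def _place_at(base, target, distance, away=(1.0, 0.0, 0.0)):
    """A point at `distance` from the named base atom, along `away`."""
    x, y = _atom_xy(base, target)
    u = np.asarray(away, float)
    u = u / np.linalg.norm(u)
    return np.array([x, y, 0.0]) + distance * u


class TestParseWrite:
    def test_round_trip_coordinates(self, tmp_path, wer_fixture):
        model, _ = wer_fixture
        path = tmp_path / "fixture.pdb"
        write_structure(model, path)
        back = parse_structure(path)
        orig = {(a.chain, a.resnum, a.name): a.pos for a in model.atoms}
        new = {(a.chain, a.resnum, a.name): a.pos for a in back.atoms}
        assert orig.keys() == new.keys()
        for key in orig:
            assert np.allclose(orig[key], new[key], atol=1e-3)

    def test_chain_classification(self, tmp_path):
        model = StructureModel(
            _base("A") + [_probe("ASN", "ND2", (10.0, 0.0, 0.0))]
        )
        assert len(model.protein_atoms) == 1
        assert len(model.nucleic_atoms) == len(BASE_TEMPLATES["A"])

    def test_altloc_first_kept(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  ND2AASN A   1       1.000   0.000   0.000  0.50 10.00           N\n"
            "ATOM      2  ND2BASN A   1       2.000   0.000   0.000  0.50 10.00           N\n"
            "END\n"
        )
        model = parse_structure(pdb)
        assert len(model.atoms) == 1
        assert model.atoms[0].pos[0] == pytest.approx(1.0, abs=1e-3)

    def test_no_nucleic_chain_warns(self, tmp_path, caplog):
        pdb = tmp_path / "prot.pdb"
        write_structure(
            StructureModel([_probe("ASN", "ND2", (0.0, 0.0, 0.0))]), pdb
        )
        with caplog.at_level("WARNING"):
            model = parse_structure(pdb)
        assert "no nucleic chain" in caplog.text
        assert find_contacts(model) == []

    def test_duplicate_atoms_rejected(self):
        a = _probe("ASN", "ND2", (0, 0, 0))
        with pytest.raises(ValueError, match="duplicate"):
            StructureModel([a, a])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            StructureModel([_probe("ASN", "ND2", (np.nan, 0, 0))])


class TestFindContacts:
    def test_asn_nd2_to_adenine_n7(self):
        model = StructureModel(
            _base("A") + [_probe("ASN", "ND2", _place_at("A", "N7", 2.9))]
        )
        hits = [c for c in find_contacts(model) if c.kind == "direct-hbond"]
        assert len(hits) == 1
        (c,) = hits
        assert c.dna_atom.name == "N7" and c.protein_atom.name == "ND2"
        assert c.distance == pytest.approx(2.9, abs=0.01)
        assert c.dna_class == "base"

    def test_leu_cd2_to_cytosine_c5_apolar(self):
        model = StructureModel(
            _base("C") + [_probe("LEU", "CD2", _place_at("C", "C5", 3.7))]
        )
        hits = find_contacts(model)
        kinds = {c.kind for c in hits}
        assert "apolar-proximity" in kinds
        (ap,) = [c for c in hits if c.kind == "apolar-proximity"
                 and c.dna_atom.name == "C5"]
        assert ap.distance == pytest.approx(3.7, abs=0.01)

    def test_empty_model(self):
        assert find_contacts(StructureModel([])) == []

    def test_complementarity_required(self):
        # donor (ND2) against donor (adenine N6): no H-bond
        model = StructureModel(
            _base("A") + [_probe("ASN", "ND2", _place_at("A", "N6", 2.9))]
        )
        assert all(
            not (c.kind == "direct-hbond" and c.dna_atom.name == "N6")
            for c in find_contacts(model)
        )

    def test_distance_cutoff(self):
        model = StructureModel(
            _base("A") + [_probe("ASN", "ND2", _place_at("A", "N7", 3.6))]
        )
        assert find_contacts(model, d_hb=3.5) == []
        assert len(find_contacts(model, d_hb=3.7)) == 1

    def test_monotonic_in_cutoffs(self, wer_fixture):
        model, _ = wer_fixture
        base = {c.signature for c in find_contacts(model, 3.5, 4.5)}
        wider = {c.signature for c in find_contacts(model, 4.0, 5.0)}
        assert base <= wider

    def test_distances_match_recomputed_euclidean(self, wer_fixture):
        model, _ = wer_fixture
        for c in find_contacts(model):
            d = np.linalg.norm(c.protein_atom.xyz() - c.dna_atom.xyz())
            assert c.distance == pytest.approx(d, abs=0.01)

    def test_equals_brute_force_on_random_models(self, rng):
        """All-pairs brute-force filter agrees with the KD-tree scan."""
        protein_pool = [("ASN", "ND2"), ("ASN", "OD1"), ("LYS", "NZ"),
                        ("LEU", "CD2"), ("SER", "OG"), ("ARG", "NH1")]
        for trial in range(10):
            atoms = list(_base("A")) + list(_base("G", key=2, offset=(8, 0, 0)))
            for i in range(12):
                resname, aname = protein_pool[int(rng.integers(len(protein_pool)))]
                pos = tuple(rng.uniform(-4, 12, size=3))
                atoms.append(_probe(resname, aname, pos, resnum=300 + i))
            model = StructureModel(atoms)
            got = {(c.protein_atom.id, c.dna_atom.id, c.kind)
                   for c in find_contacts(model)}
            expected = set()
            for p, d in itertools.product(model.protein_atoms, model.nucleic_atoms):
                dist = np.linalg.norm(p.xyz() - d.xyz())
                proles = chem.protein_polar_roles(p.resname, p.name)
                droles = chem.dna_polar_roles(d.resname, d.name)
                if proles and droles and dist <= 3.5 and (
                    (chem.DONOR in proles and chem.ACCEPTOR in droles)
                    or (chem.ACCEPTOR in proles and chem.DONOR in droles)
                ):
                    expected.add((p.id, d.id, "direct-hbond"))
                if (chem.protein_is_apolar(p.resname, p.name) and dist <= 4.5
                        and chem.dna_is_base_carbon(d.resname, d.name)):
                    expected.add((p.id, d.id, "apolar-proximity"))
            assert got == expected


class TestWaterBridges:
    def _bridge_model(self, extra=()):
        # water equidistant 2.8 Å from Asn OD1 and thymine O4
        x, y = _atom_xy("T", "O4")
        u = np.array([0.789, -0.615, 0.0])
        water = np.array([x, y, 0]) + 2.8 * u
        probe = np.array([x, y, 0]) + 5.6 * u
        atoms = (
            _base("T")
            + [Atom("W", 901, "HOH", "O", "O", tuple(water))]
            + [_probe("ASN", "OD1", probe)]
            + list(extra)
        )
        return StructureModel(atoms)

    def test_single_bridge(self):
        bridges = find_water_bridges(self._bridge_model())
        assert len(bridges) == 1
        (b,) = bridges
        assert b.kind == "water-mediated"
        assert b.dna_atom.name == "O4" and b.protein_atom.name == "OD1"
        assert b.distance == pytest.approx(2.8, abs=0.01)
        assert b.bridging_water is not None

    def test_water_near_only_protein_no_bridge(self):
        atoms = [
            _probe("ASN", "OD1", (50.0, 0.0, 0.0)),
            Atom("W", 902, "HOH", "O", "O", (52.0, 0.0, 0.0)),
        ] + _base("T")
        assert find_water_bridges(StructureModel(atoms)) == []

    def test_two_waters_bridging_same_pair_two_records(self):
        x, y = _atom_xy("T", "O4")
        u = np.array([0.789, -0.615, 0.0])
        # second water 2.8 Å from O4, rotated 20° from the first; still
        # within 3.5 Å of the probe sitting at 5.6 Å along u
        theta = np.deg2rad(20)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        second = np.array([x, y, 0]) + 2.8 * (rot @ u)
        model = self._bridge_model(
            extra=[Atom("W", 902, "HOH", "O", "O", tuple(second))]
        )
        bridges = find_water_bridges(model)
        assert len(bridges) == 2
        assert {b.bridging_water.resnum for b in bridges} == {901, 902}
        assert len({(b.protein_atom.id, b.dna_atom.id) for b in bridges}) == 1


class TestReadoutMap:
    def test_base_specific_vs_backbone(self):
        base = _base("A")
        phosphate = Atom("D", 1, "DA", "OP1", "O", (-4.0, 6.0, 0.0))
        model = StructureModel(
            base
            + [phosphate]
            + [_probe("ASN", "ND2", _place_at("A", "N7", 2.9), resnum=110),
               _probe("LYS", "NZ", (-4.0, 6.0, 2.9), resnum=55)]
        )
        contacts = find_contacts(model)
        rmap = readout_map(contacts)
        assert rmap["dna_residues"]["D/DA1"]["label"] == "base-specific"
        assert "ASN110" in rmap["helices"]["H6"]
        # LYS55 touches only the phosphate: not a base reader of H3
        assert "LYS55" not in rmap["helices"]["H3"]

    def test_phosphate_only_backbone_label(self):
        atoms = [
            Atom("D", 1, "DA", "OP1", "O", (0.0, 0.0, 0.0)),
            _probe("LYS", "NZ", (2.9, 0.0, 0.0), resnum=52),
        ]
        rmap = readout_map(find_contacts(StructureModel(atoms)))
        assert rmap["dna_residues"]["D/DA1"]["label"] == "backbone-only"

    def test_empty_contacts(self):
        rmap = readout_map([])
        assert rmap["dna_residues"] == {} and rmap["helices"] == {"H3": [], "H6": []}


class TestMethylSensitivity:
    def test_5mc_flag_from_apolar_packing(self):
        model = StructureModel(
            _base("C") + [_probe("LEU", "CD2", _place_at("C", "C5", 3.7))]
        )
        contacts = find_contacts(model)
        sites = predict_methyl_sensitivity(model, contacts)
        assert [(s.modification, s.mechanism) for s in sites] == [
            ("5mC", "steric-clash")
        ]

    def test_5mc_flag_from_virtual_methyl_clash(self):
        # probe placed right where the 5-methyl carbon would go
        c4 = np.array([*_atom_xy("C", "C4"), 0.0])
        c5 = np.array([*_atom_xy("C", "C5"), 0.0])
        vm = virtual_methyl_position(c4, c5)
        # an apolar carbon hovering over C5 both marks the base as read out
        # and sits where the 5-methyl carbon would go
        model = StructureModel(
            _base("C")
            + [_probe("ALA", "CB", vm + np.array([0.0, 0.0, 2.0]), resnum=501)]
        )
        contacts = find_contacts(model)
        sites = predict_methyl_sensitivity(model, contacts)
        assert any(s.modification == "5mC" for s in sites)
        (site,) = [s for s in sites if s.modification == "5mC"]
        assert any("virtual-5-methyl" in e for e in site.evidence)

    def test_6ma_flag_requires_n6_donation(self):
        n6_model = StructureModel(
            _base("A") + [_probe("ASN", "OD1", _place_at("A", "N6", 3.0))]
        )
        sites = predict_methyl_sensitivity(n6_model, find_contacts(n6_model))
        assert [(s.modification, s.mechanism) for s in sites] == [
            ("6mA", "donor-occlusion")
        ]
        # adenine contacted only via N7: no 6mA flag
        n7_model = StructureModel(
            _base("A") + [_probe("ASN", "ND2", _place_at("A", "N7", 2.9))]
        )
        sites = predict_methyl_sensitivity(n7_model, find_contacts(n7_model))
        assert sites == []

    def test_virtual_methyl_geometry(self):
        c4 = np.zeros(3)
        c5 = np.array([1.4, 0.0, 0.0])
        vm = virtual_methyl_position(c4, c5, bond=1.5)
        assert np.allclose(vm, [2.9, 0.0, 0.0])


class TestFixtureExactness:
    def test_composite_fixture_recovers_planted_contacts(self, wer_fixture):
        model, truth = wer_fixture
        got = {(c.protein_atom.id, c.dna_atom.id, c.kind)
               for c in find_contacts(model)}
        planted = {(c["protein"], c["dna"], c["kind"])
                   for c in truth["planted_contacts"]}
        assert got == planted

    def test_requested_distances_exact(self, wer_fixture):
        model, truth = wer_fixture
        by_pair = {
            (c.protein_atom.id, c.dna_atom.id): c.distance
            for c in find_contacts(model)
        }
        for c in truth["planted_contacts"]:
            assert by_pair[(c["protein"], c["dna"])] == pytest.approx(
                c["distance"], abs=0.01
            )

    def test_unrealizable_geometry_rejected(self):
        # an H-bond placement against a non-polar DNA atom can never be
        # realized; the builder's self-check must refuse it
        with pytest.raises(ValueError, match="missing"):
            build_fixture(
                [Placement("C", "C1", "C5", "ASN", "ND2", 2.9, kind="direct")]
            )
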