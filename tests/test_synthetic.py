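"""Ground-truthed generators: genome, methylome, fixtures, thermograms."""

import numpy as np
import pytest
from scipy import stats

from mybdna import MotifPattern, attach_methylation, scan_motifs, tally_census
from mybdna.isotherm import BindingParameters, TitrationProtocol
from mybdna.synthetic import (
    BASE_TEMPLATES,
    Placement,
    build_fixture,
    gen_genome,
    gen_methylome,
    gen_thermograms,
    oracle_scan,
    wer_interface_placements,
    write_genome_bundle,
)


class TestGenGenome:
    def test_planted_recovery(self):
        b = gen_genome(n_chrom=1, chrom_len=10_000, n_genes=3,
                       n_planted_motifs=5, seed=7)
        hits = {h.key for h in scan_motifs(b.genome, MotifPattern("AACNDN"),
                                           b.promoters)}
        planted = {(p["chrom"], p["start"], p["end"], p["strand"])
                   for p in b.truth["planted"]}
        assert planted <= hits

    def test_gc_zero_background_all_at(self):
        b = gen_genome(n_chrom=1, chrom_len=2_000, n_genes=1,
                       n_planted_motifs=0, gc=0.0, seed=1)
        assert set(b.genome["chr1"].seq) <= {"A", "T"}

    def test_seed_determinism_bytes(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            b = gen_genome(n_chrom=1, chrom_len=5_000, n_genes=2,
                           n_planted_motifs=10, seed=42)
            write_genome_bundle(b, out)
        for name in ("genome.fa", "genes.gff3", "genome.truth.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_planted_sequences_match_pattern(self, small_bundle):
        pat = MotifPattern(small_bundle.truth["pattern"])
        for p in small_bundle.truth["planted"]:
            assert pat.matches(p["seq"])
            # and the genome slice realizes the motif on the right strand
            sl = small_bundle.genome[p["chrom"]].seq[p["start"]:p["end"]]
            from mybdna import reverse_complement

            motif_strand = sl if p["strand"] == "+" else reverse_complement(sl)
            assert motif_strand == p["seq"]

    def test_planted_inside_promoters(self, small_bundle):
        windows = small_bundle.promoters
        for p in small_bundle.truth["planted"]:
            assert any(
                w.chrom == p["chrom"] and w.start <= p["start"]
                and p["end"] <= w.end for w in windows
            )

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError, match="gc"):
            gen_genome(gc=1.5)


class TestGenMethylome:
    def test_all_zero_rates_empty(self, small_bundle):
        c5, c6, truth = gen_methylome(
            small_bundle.genome, small_bundle.truth,
            p_5mC_pos3=0, p_6mA_pos1=0, p_6mA_pos2=0, p_background=0, seed=1,
        )
        assert c5 == [] and c6 == []
        assert all(
            not any(f.values()) for f in truth["methylome"]["effective_flags"]
        )

    def test_saturated_5mc_flags_every_motif(self, small_bundle):
        c5, c6, truth = gen_methylome(
            small_bundle.genome, small_bundle.truth,
            p_5mC_pos3=1.0, p_6mA_pos1=0, p_6mA_pos2=0, p_background=0, seed=1,
        )
        instances = scan_motifs(
            small_bundle.genome, MotifPattern("AACNDN"), small_bundle.promoters
        )
        census = tally_census(
            attach_methylation(instances, c5 + c6), small_bundle.promoters
        )
        planted = {(p["chrom"], p["start"], p["end"], p["strand"])
                   for p in small_bundle.truth["planted"]}
        assert census["5mC_pos3"] >= len(planted)

    def test_calls_sit_on_chemically_valid_bases(self, small_bundle):
        c5, c6, _ = gen_methylome(
            small_bundle.genome, small_bundle.truth, p_background=0.01, seed=4
        )
        for call in c5:
            base = small_bundle.genome[call.chrom].seq[call.pos]
            assert base == ("C" if call.strand == "+" else "G")
        for call in c6:
            base = small_bundle.genome[call.chrom].seq[call.pos]
            assert base == ("A" if call.strand == "+" else "T")

    def test_drawn_flag_rates_within_binomial_99pct_bounds(self):
        b = gen_genome(n_chrom=1, chrom_len=1_000_000, n_genes=300,
                       n_planted_motifs=2000, seed=3)
        rates = {"5mC_pos3": 0.1, "6mA_pos1": 0.005, "6mA_pos2": 0.015}
        _, _, truth = gen_methylome(
            b.genome, b.truth,
            p_5mC_pos3=rates["5mC_pos3"], p_6mA_pos1=rates["6mA_pos1"],
            p_6mA_pos2=rates["6mA_pos2"], p_background=0.0, seed=3,
        )
        drawn = truth["methylome"]["drawn_flags"]
        n = len(drawn)
        for key, p in rates.items():
            count = sum(f[f"{key.split('_')[0]}_pos{key[-1]}"] for f in drawn)
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= count <= hi, f"{key}: {count} outside [{lo},{hi}]"


class TestBaseTemplates:
    RING_BONDS = {
        "A": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
              ("C6", "N6"), ("C6", "N1"), ("N1", "C2"), ("C2", "N3"),
              ("N3", "C4"), ("C4", "N9"), ("C4", "C5")],
        "G": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
              ("C6", "O6"), ("C6", "N1"), ("N1", "C2"), ("C2", "N2"),
              ("C2", "N3"), ("N3", "C4"), ("C4", "N9"), ("C4", "C5")],
        "C": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"),
              ("C4", "N4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1")],
        "T": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"),
              ("C4", "O4"), ("C4", "C5"), ("C5", "C7"), ("C5", "C6"),
              ("C6", "N1")],
    }

    def test_covalent_bond_lengths_near_standard(self):
        """Intra-base bond lengths sit within 0.1 Å of standard aromatic/
        single-bond values (1.23-1.55 Å window)."""
        for base, bonds in self.RING_BONDS.items():
            coords = {n: np.array([x, y]) for n, x, y in BASE_TEMPLATES[base]}
            for a, b in bonds:
                d = np.linalg.norm(coords[a] - coords[b])
                assert 1.23 - 0.1 <= d <= 1.55 + 0.1, f"{base} {a}-{b}: {d:.3f}"


class TestBuildFixture:
    def test_requested_distance_exact(self):
        model, truth = build_fixture(
            [Placement("A", "a", "N7", "ASN", "ND2", 2.9)]
        )
        (probe,) = model.protein_atoms
        n7 = model.residue_atoms(("D", 1, "DA"))["N7"]
        d = np.linalg.norm(probe.xyz() - n7.xyz())
        assert d == pytest.approx(2.9, abs=0.01)
        assert len(truth["planted_contacts"]) == 1

    def test_empty_spec_valid(self):
        model, truth = build_fixture([])
        assert model.atoms == [] and truth["planted_contacts"] == []

    def test_composite_interface_truth_schema(self, wer_fixture):
        _, truth = wer_fixture
        kinds = [c["kind"] for c in truth["planted_contacts"]]
        assert kinds.count("direct-hbond") == 6
        assert kinds.count("apolar-proximity") == 1
        assert truth["n_bases"] == 5

    def test_unknown_base_rejected(self):
        with pytest.raises(ValueError, match="unknown base"):
            build_fixture([Placement("X", "x", "N7", "ASN", "ND2", 2.9)])


class TestGenThermograms:
    def test_determinism_and_truth(self):
        grid = [BindingParameters(n=1.0, kd=0.051, dh=-8000.0)]
        a, truth_a = gen_thermograms(grid, TitrationProtocol(),
                                     noise_sd=0.3, reps=3, seed=9)
        b, _ = gen_thermograms(grid, TitrationProtocol(),
                               noise_sd=0.3, reps=3, seed=9)
        assert [t.heats for _, _, t in a] == [t.heats for _, _, t in b]
        assert len(a) == 3
        assert truth_a["parameter_sets"][0]["kd_uM"] == 0.051
        # distinct replicates differ
        assert a[0][2].heats != a[1][2].heats


class TestOracleIndependence:
    def test_oracle_scan_on_known_string(self):
        from mybdna.sequences import GenomeSequence

        genome = {"c": GenomeSequence("c", "AAATTCTCCAACCGCATTTTC")}
        hits = oracle_scan(genome, "AACNDN")
        assert hits == {("c", 9, 15, "+", "AACCGC")}
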