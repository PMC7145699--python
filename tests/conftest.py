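import numpy as np
import pytest

from mybdna import synthetic


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic genome bundle shared by read-only tests."""
    return synthetic.gen_genome(
        n_chrom=2, chrom_len=20_000, n_genes=6, n_planted_motifs=20, seed=7
    )


@pytest.fixture(scope="session")
def wer_fixture():
    """The composite interface fixture mirroring the printed readout
    geometries (model, truth)."""
    return synthetic.build_fixture(synthetic.wer_interface_placements())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
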