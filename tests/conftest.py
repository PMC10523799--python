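import pytest

from acetrank.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """A compact simulated dataset shared by read-only tests."""
    return simulate(
        SimConfig(
            seed=11,
            n_typical_peaks=150,
            n_se_clusters=3,
            n_genes=80,
            chrom_lengths=(("chrS1", 8_000_000), ("chrS2", 8_000_000)),
        )
    )


@pytest.fixture(scope="session")
def sim_small_paths(sim_small, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return sim_small.write(outdir)
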