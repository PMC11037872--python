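import numpy as np
import pytest

from sdfam import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A cohort config small enough for per-test simulation."""
    return simulate.SimConfig(
        seed=11,
        n_samples=3,
        populations=[
            simulate.PopulationSpec("AFR", cn_mean=8.6),
            simulate.PopulationSpec("NONAFR", cn_mean=6.35),
        ],
        n_clusters=2,
        n_paralog_groups=2,
        cassette_length_bp=4000,
        unit_gene_length_bp=2000,
        flank_length_bp=1500,
    )


@pytest.fixture
def small_cohort(small_config):
    return simulate.make_population(small_config)
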