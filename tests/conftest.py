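import numpy as np
import pytest

from delimix import SimConfig, sim_world


@pytest.fixture(scope="session")
def small_world():
    """A compact crossing-scenario world shared by read-only tests."""
    return sim_world(SimConfig(samples_per_pop=8, n_snp_loci=300, seed=11))


@pytest.fixture(scope="session")
def default_world():
    """The reference study conditions (4 lineages, c=0.25, 15/pop, 1000 SNPs)."""
    return sim_world(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
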