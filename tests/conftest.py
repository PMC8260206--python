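import numpy as np
import pytest

import glandphylo as gp


@pytest.fixture(scope="session")
def default_gland():
    """The default synthetic gland at a fixed seed (shared; expensive)."""
    return gp.simulate_gland(gp.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_cluster_result(default_gland):
    """DP clustering of the default gland (shared; expensive)."""
    return gp.cluster_mutations(
        default_gland.vaf_matrix, gp.ClusterConfig(seed=1)
    )


@pytest.fixture(scope="session")
def small_gland():
    """A small gland for fast structural tests."""
    cfg = gp.SimulationConfig(seed=7, n_terminal_acini=6, n_microdissections=8)
    return gp.simulate_gland(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
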