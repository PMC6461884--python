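import numpy as np
import pytest

from tgcevo.config import SimConfig
from tgcevo.simulate.io import simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A light configuration for fast end-to-end runs."""
    return SimConfig(n_clones=4, n_samples=4, snv_rate=0.01,
                     amplicons_per_arm=1, snps_per_amplicon=2,
                     depth_median=300, seed=11).validate()


@pytest.fixture
def small_result(small_config):
    return simulate_all(small_config)
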