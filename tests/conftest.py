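import numpy as np
import pytest

from famtrait.simulate import SimConfig, make_dataset


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 60 species, 150 families, same causal structure."""
    return SimConfig(n_species=60, n_families=150, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
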