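import numpy as np
import pytest

from nirtransfer.synthdata import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast synthetic configuration shared across tests."""
    return SyntheticConfig(n_samples=60, n_points=120, seed=7)


@pytest.fixture(scope="session")
def small_source(small_cfg):
    return generate(small_cfg, 10.0)


@pytest.fixture(scope="session")
def small_target(small_cfg):
    return generate(small_cfg, 70.0)
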