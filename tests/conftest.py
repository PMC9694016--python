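import numpy as np
import pytest

from musyn import NestedScenarioConfig, nested_scenario


@pytest.fixture(scope="session")
def rank3_matrix():
    """A random nonnegative 8x60 matrix of exact rank 3."""
    rng = np.random.default_rng(42)
    W = rng.uniform(0.0, 1.0, size=(8, 3))
    C = rng.uniform(0.0, 1.0, size=(3, 60))
    return W @ C


@pytest.fixture(scope="session")
def noiseless_nested():
    """Nested 12-in-32 dataset with no noise and no tonic component."""
    cfg = NestedScenarioConfig(noise_sigma=0.0, tonic_max=0.0, seed=3)
    return nested_scenario(cfg)


@pytest.fixture(scope="session")
def noisy_nested():
    """Nested dataset under the default moderate-noise conditions."""
    return nested_scenario(NestedScenarioConfig(seed=5))
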