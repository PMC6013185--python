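import numpy as np
import pytest

from omicscreen import ScenarioSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One p=205 dataset at rho=0.4, n=30 (shared, read-only)."""
    spec = ScenarioSpec(block_size=35, noise_count=100, rho=0.4, n_total=30)
    return simulate_dataset(spec, np.random.default_rng(123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
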