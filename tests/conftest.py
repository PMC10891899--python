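import numpy as np
import pytest

from hsvein import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Six noiseless 64x64x64 scenes under uniform illumination."""
    cfg = SyntheticConfig(noise_sigma=0.0, illumination_strength=0.0, seed=7)
    return generate_dataset(cfg, 6)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same geometry with sigma = 0.02 detector noise."""
    cfg = SyntheticConfig(noise_sigma=0.02, illumination_strength=0.0, seed=7)
    return generate_dataset(cfg, 6)
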