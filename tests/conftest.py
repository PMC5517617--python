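import numpy as np
import pytest

from isletscope import SynthConfig, generate_islet_volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_volume():
    """A small noisy two-channel volume with 8 well-separated islets."""
    cfg = SynthConfig(
        volume_shape=(120, 120, 60),
        n_islets=8,
        min_center_separation=100.0,
        seed=3,
    )
    islet_ch, nerve_ch, truth = generate_islet_volume(cfg)
    return islet_ch, nerve_ch, truth


@pytest.fixture(scope="session")
def clean_volume():
    """A noiseless volume of 12 spheres for exact recovery checks."""
    cfg = SynthConfig(
        volume_shape=(160, 160, 80),
        n_islets=12,
        radius_distribution={"name": "uniform", "low": 15.0, "high": 75.0},
        min_center_separation=150.0,
        background_noise=0.0,
        seed=11,
    )
    islet_ch, nerve_ch, truth = generate_islet_volume(cfg)
    return islet_ch, nerve_ch, truth
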