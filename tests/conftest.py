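import numpy as np
import pytest

from tirfkit import SimConfig, TwoPopulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A small, quiet acquisition for fast image tests."""
    return SimConfig(
        seed=11, n_frames=5, image_shape=(64, 64), noise_sd=0.0, psf_sigma_px=1.3
    )


@pytest.fixture
def aptes_params():
    return TwoPopulationParams(
        alpha_mobile=0.57, d_mobile_um2_s=5.1e-4, d_immobile_um2_s=1e-5
    )
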