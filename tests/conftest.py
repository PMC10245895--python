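import numpy as np
import pytest
from scipy import ndimage as ndi

from cordmotion.movie import MovieTensor
from cordmotion.synthetic import SimConfig, make_movie


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def textured_frame():
    """A band-limited scalar test image with structure at several scales."""
    r = np.random.default_rng(42)
    return ndi.gaussian_filter(r.random((128, 128)), 2.0) * 100.0


@pytest.fixture(scope="session")
def quiet_sim():
    """Small noise-free, motion-free simulated movie plus ground truth."""
    cfg = SimConfig(
        shape=(96, 96), n_frames=8, max_rc_shift_px=0.0, jitter_sigma_px=0.0,
        deform_amp_px=0.0, occluder_opacity=0.0, bleach_rate=0.0,
        photon_scale=0.0, read_noise_sigma=0.0, cells_per_side=5, seed=11,
    )
    return make_movie(cfg)


@pytest.fixture(scope="session")
def moving_sim():
    """Simulated movie with large rostrocaudal shifts, occluder, and noise."""
    cfg = SimConfig(
        shape=(128, 128), n_frames=25, max_rc_shift_px=50.0, jitter_sigma_px=0.3,
        deform_amp_px=0.0, occluder_opacity=0.4, photon_scale=0.5,
        read_noise_sigma=1.0, seed=1,
    )
    return make_movie(cfg)


@pytest.fixture
def small_movie(rng):
    return MovieTensor(rng.random((6, 16, 16)) * 50 + 10, frame_rate=10.0)
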