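import numpy as np
import pytest

from bayestrack import (
    CameraEMCCD,
    CameraSPAD,
    MotionParams,
    OpticsConfig,
    Priors,
)
from bayestrack.motion import fov_for_frame


@pytest.fixture
def optics():
    return OpticsConfig(
        numerical_aperture=1.45,
        refractive_index=1.515,
        emission_wavelength_nm=665.0,
        pixel_size_nm=133.0,
    )


@pytest.fixture
def emccd():
    return CameraEMCCD(offset=100.0, em_gain=100.0, read_noise_sd=2.0)


@pytest.fixture
def spad():
    return CameraSPAD()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def motion():
    return MotionParams(msd_per_frame_nm2=13_200.0)


def make_priors(frame_shape=(8, 8), pixel_size_nm=133.0, **kw):
    defaults = dict(
        msd_shape=2.0,
        msd_scale_nm2=13_200.0,
        load_prob=0.5,
        fov_bounds=fov_for_frame(frame_shape, pixel_size_nm),
    )
    defaults.update(kw)
    return Priors(**defaults)


@pytest.fixture
def priors():
    return make_priors()
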