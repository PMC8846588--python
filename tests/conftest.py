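import numpy as np
import pytest

from throughcuticle.core import (
    AcquisitionParams,
    AttenuationProfile,
    PowerSchedule,
    PSFModel,
    ScenePhantom,
    Slab,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def slab_phantom():
    """Uniform slab filling a 21-plane, 32x32 grid at 5 um z-steps."""
    nz = 21
    return ScenePhantom((nz, 32, 32), 0.5, 5.0, [Slab(0.0, (nz - 1) * 5.0)])


@pytest.fixture
def single_layer_attenuation():
    return AttenuationProfile([(0.0, 200.0, 50.0)], excitation_order=2)


@pytest.fixture
def narrow_psf():
    """PSF narrow enough that blur does not couple depth planes."""
    return PSFModel(lateral_sigma_um=0.5, axial_hw_um=0.4, axial_power=3)


@pytest.fixture
def flat_schedule():
    return PowerSchedule(np.array([0.0, 200.0]), np.array([10.0, 10.0]))


@pytest.fixture
def params_3p():
    return AcquisitionParams(1320.0, 3, 400e3, pixel_dwell_s=1e-6)


@pytest.fixture
def params_2p():
    return AcquisitionParams(920.0, 2, 80e6, pulse_width_fs=100.0, pixel_dwell_s=1e-6)
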