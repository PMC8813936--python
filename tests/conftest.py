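import numpy as np
import pytest

from cyclim import (AcquisitionPlan, CrosstalkMatrix, CyclePlan, NoiseModel,
                    make_bead_scene)


@pytest.fixture
def noise():
    """Quiet camera: offset 100, sigma 2, effectively no saturation."""
    return NoiseModel(read_offset=100.0, read_sigma=2.0, gain=1.0,
                      saturation_level=1e9)


@pytest.fixture
def camera_16bit():
    """Realistic 16-bit camera with hard saturation."""
    return NoiseModel(read_offset=100.0, read_sigma=2.0, gain=1.0,
                      saturation_level=65535.0)


@pytest.fixture
def two_channel_plan():
    ct = CrosstalkMatrix(np.array([[1.0, 0.08], [0.12, 1.0]]), ["DAPI", "APC"])
    return AcquisitionPlan(
        cycles=[CyclePlan(stains={"APC": "APC", "DAPI": "DAPI"}, prestain=False)],
        crosstalk=ct,
    )


@pytest.fixture
def bead_scene():
    return make_bead_scene(6, 0.5, 10_000, bead_radius=30,
                           field_size=(384, 384), seed=7)


@pytest.fixture
def textured_image():
    from scipy import ndimage
    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.normal(0.0, 1.0, (192, 192)), 2.0)
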