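import numpy as np
import pytest

from dynfet import (
    DynamicPETSeries,
    RegionMask,
    VolumeImage,
    default_frame_schema,
    generate_phantom,
)
from dynfet.simulate import PLATEAU_TAC, WASHOUT_TAC


@pytest.fixture(scope="session")
def schema():
    return default_frame_schema()


def make_uniform_series(frame_values, shape=(6, 8, 8), spacing=(2.0, 2.0, 2.0)):
    """A spatially uniform series whose TAC is exactly ``frame_values``."""
    schema = default_frame_schema()
    vals = np.asarray(frame_values, dtype=float)
    assert len(vals) == len(schema)
    voxels = np.broadcast_to(
        vals[:, None, None, None], (len(vals),) + shape
    ).copy()
    return DynamicPETSeries(voxels, spacing, schema)


@pytest.fixture
def uniform_series():
    return make_uniform_series(np.linspace(1.0, 2.5, 16))


def ball_image(radius_mm, spacing=(2.0, 2.0, 2.0), inside=3.2, outside=1.0,
               margin_vox=3):
    """A digital ball of uniform uptake, centred on a voxel centre."""
    half = int(np.ceil(radius_mm / min(spacing))) + margin_vox
    n = 2 * half + 1
    z, y, x = np.meshgrid(
        *[(np.arange(n) - half) * s for s in spacing], indexing="ij"
    )
    ball = z**2 + y**2 + x**2 <= radius_mm**2
    img = np.where(ball, inside, outside)
    return VolumeImage(img, spacing), ball, (half, half, half)


@pytest.fixture(scope="session")
def noiseless_washout_phantom():
    return generate_phantom(tumour_tac=WASHOUT_TAC, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_plateau_phantom():
    return generate_phantom(tumour_tac=PLATEAU_TAC, noise_sigma=0.0, seed=0)


def full_mask(shape, spacing=(2.0, 2.0, 2.0)):
    return RegionMask(np.ones(shape, dtype=bool), spacing)
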