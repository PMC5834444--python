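import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petavid.segmentation import Region
from petavid.volumes import SUVVolume

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def region_from_mask(mask, suv, spacing=5.0, region_id=1):
    """Build a Region from a boolean mask and an SUV array on the same grid."""
    idx = np.argwhere(mask)
    return Region(
        id=region_id,
        voxel_indices=idx,
        suv_values=np.asarray(suv)[idx[:, 0], idx[:, 1], idx[:, 2]],
        spacing=spacing,
        grid_shape=mask.shape,
    )


def region_from_values(values, shape=None, spacing=5.0):
    """Region occupying a dense block with the given SUV values."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, 1, 1)
    if shape is None:
        shape = values.shape
    mask = np.zeros(shape, dtype=bool)
    mask[: values.shape[0], : values.shape[1], : values.shape[2]] = True
    suv = np.zeros(shape)
    suv[: values.shape[0], : values.shape[1], : values.shape[2]] = values
    return region_from_mask(mask, suv, spacing=spacing)


def sphere_mask(shape, center, radius):
    grids = np.ogrid[[slice(0, n) for n in shape]]
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_random_region(rng):
    """A 6x5x4 region with smooth-ish random SUVs."""
    shape = (8, 7, 6)
    mask = np.zeros(shape, dtype=bool)
    mask[1:7, 1:6, 1:5] = rng.random((6, 5, 4)) > 0.25
    mask[2, 2, 2] = True  # guarantee non-empty
    suv = rng.uniform(3.0, 9.0, size=shape)
    return region_from_mask(mask, suv)


def make_suv(voxels, spacing=5.0):
    return SUVVolume(np.asarray(voxels, dtype=float), (spacing,) * 3)
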