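import numpy as np
import pytest

from svdquant.phantom import PhantomSpec, generate_phantom
from svdquant.volumes import BinaryMask, GridRef, VolumeGrid


@pytest.fixture(scope="session")
def phantom_noisy():
    """Standard phantom at the default 2%-of-range noise level."""
    return generate_phantom(PhantomSpec(seed=7, noise_sd_fraction=0.02))


@pytest.fixture(scope="session")
def phantom_clean():
    """Zero-noise phantom with the full feature load."""
    return generate_phantom(PhantomSpec(seed=7, noise_sd_fraction=0.0))


@pytest.fixture(scope="session")
def phantom_plain():
    """Zero-noise phantom with no focal features (pure tissue classes)."""
    return generate_phantom(PhantomSpec(
        seed=7, noise_sd_fraction=0.0, include_wmh=False,
        include_lesion=False, include_vessel=False,
        microbleed_centers_mm=(), iron_radius_mm=0.0))


def make_grid(shape=(16, 16, 8), spacing=(1.0, 1.0, 1.0)):
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    return GridRef(shape=tuple(shape), spacing=tuple(spacing), affine=affine)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    grid = make_grid(np.asarray(data).shape, spacing)
    return BinaryMask(np.asarray(data, bool), grid)


def make_volume(data, spacing=(1.0, 1.0, 1.0), tag=""):
    grid = make_grid(np.asarray(data).shape, spacing)
    return VolumeGrid(np.asarray(data, float), affine=grid.affine,
                      spacing=grid.spacing, modality_tag=tag)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    s = a.n_voxels + b.n_voxels
    return 2.0 * int((a.data & b.data).sum()) / s if s else 1.0
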