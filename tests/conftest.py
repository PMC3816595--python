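import dataclasses

import numpy as np
import pytest

from dirprop.image_model import ImageGrid, ROIMask, ScalarImage
from dirprop.phantom import (
    PhantomSpec,
    gaussian_bump_deformation,
    make_deformed_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_grid():
    return ImageGrid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def ct_grid():
    # CT-like anisotropic spacing
    return ImageGrid((32, 32, 12), (0.98, 0.98, 3.0))


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Phantom on a coarse 64 x 64 x 24 grid (same 256 x 256 x 144 mm FOV)."""
    defaults = dict(grid=ImageGrid((64, 64, 24), (4.0, 4.0, 6.0)))
    defaults.update(overrides)
    return dataclasses.replace(PhantomSpec(), **defaults)


@pytest.fixture(scope="session")
def small_pair():
    """Deformed small-phantom pair shared by the registration unit tests."""
    spec = small_phantom_spec()
    deformation = gaussian_bump_deformation(
        (4.2, 4.2, 0.0), spec.tumour.center, 30.0
    )
    return make_deformed_pair(spec, deformation)


def random_blob_mask(grid: ImageGrid, rng, name="blob") -> ROIMask:
    """A random smooth blob mask (possibly empty) for metric tests."""
    centers = grid.voxel_centers()
    center = grid.index_to_world(rng.uniform(0.2, 0.8, 3) * np.asarray(grid.dims))
    radii = rng.uniform(0.15, 0.45, 3) * np.asarray(grid.dims) * np.asarray(grid.spacing)
    d = (centers - center) / radii
    return ROIMask(grid, (d * d).sum(axis=-1) <= 1.0, name)
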