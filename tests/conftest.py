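import numpy as np
import pytest

from formfactors import PhantomSpec, VoxelMask, make_phantom


@pytest.fixture(scope="session")
def sphere_mask():
    """Voxelised sphere, radius 10 mm at 0.5 mm spacing (fine resolution)."""
    return make_phantom(PhantomSpec(semi_axes=(10, 10, 10), spacing=(0.5,) * 3))


@pytest.fixture(scope="session")
def ellipsoid_mask():
    """Voxelised axis-aligned ellipsoid, semi-axes (10, 5, 2.5) mm at 0.5 mm."""
    return make_phantom(PhantomSpec(semi_axes=(10, 5, 2.5), spacing=(0.5,) * 3))


@pytest.fixture(scope="session")
def cuboid_mask():
    """Solid 20 x 10 x 5 voxel cuboid at unit spacing."""
    return make_phantom(
        PhantomSpec(shape="cuboid", semi_axes=(10, 5, 2.5), spacing=(1.0,) * 3)
    )


@pytest.fixture
def single_voxel_mask():
    grid = np.zeros((5, 5, 5))
    grid[2, 2, 2] = 1
    return VoxelMask(grid=grid, spacing=(1.0, 1.0, 1.0))
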