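import numpy as np
import pytest

from dualale.ale_maps import KernelSpec
from dualale.pipeline import packaged_study_table
from dualale.stereotax import VoxelGrid, make_grid
from dualale.study_io import parse_study_table


def full_mask_grid(n: int = 10, voxel_size: float = 2.0) -> VoxelGrid:
    """Small fully-unmasked cubic grid centered on the origin, for oracles."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = -voxel_size * (n - 1) / 2.0
    return VoxelGrid(
        shape=(n, n, n),
        affine=affine,
        voxel_size=voxel_size,
        mask=np.ones((n, n, n), dtype=bool),
    )


@pytest.fixture(scope="session")
def tiny_grid() -> VoxelGrid:
    return full_mask_grid(10, 2.0)


@pytest.fixture(scope="session")
def grid4() -> VoxelGrid:
    """4 mm whole-brain grid with the procedural ellipsoid mask."""
    return make_grid(4.0)


@pytest.fixture(scope="session")
def kernel10() -> KernelSpec:
    return KernelSpec(fwhm=10.0)


@pytest.fixture(scope="session")
def table2_records():
    return parse_study_table(packaged_study_table())
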