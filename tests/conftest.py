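import numpy as np
import pytest

from soctmi import StructureSet, VoxelGrid
from soctmi.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def water_grid():
    """40 mm cube of water at 1 mm spacing, voxel centers at (i + 1/2) mm."""
    n = 40
    return VoxelGrid(np.ones((n, n, n)), (1.0, 1.0, 1.0), (0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def default_phantom():
    """The reference mouse at the 1 mm planning resolution."""
    cfg = PhantomConfig(spacing=(1.0, 1.0, 1.0), seed=0, jitter_mm=0.5)
    return generate_phantom(cfg)


@pytest.fixture()
def body_only_structures(water_grid):
    body = np.ones(water_grid.dims, dtype=bool)
    empty = np.zeros(water_grid.dims, dtype=bool)
    return StructureSet(water_grid, {"body": body, "skeleton": empty.copy(),
                                     "spleen": empty.copy()})
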