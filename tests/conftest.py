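import numpy as np
import pytest

from wallvol.grid import VoxelGrid
from wallvol.synthetic import CellSpec, GridSpec, rasterize_cell, simulate_stack


@pytest.fixture
def iso_grid() -> GridSpec:
    """Small isotropic lattice (0.1 μm voxels, 6 μm cube)."""
    return GridSpec(shape=(60, 60, 60), spacing=(0.1, 0.1, 0.1))


@pytest.fixture
def aniso_grid() -> GridSpec:
    """Confocal-like anisotropic lattice (0.2 μm z, 0.08 μm xy)."""
    return GridSpec(shape=(42, 104, 104), spacing=(0.2, 0.08, 0.08))


@pytest.fixture
def shell_cell(iso_grid) -> CellSpec:
    return CellSpec(
        center=(3.0, 3.0, 3.0), outer_radius=2.2, wall_thickness=0.5, intensity=100.0
    )


@pytest.fixture
def shell_fixture(shell_cell, iso_grid):
    """(mask, truth, noiseless unblurred stack) of one shell cell."""
    mask, truth = rasterize_cell(shell_cell, iso_grid)
    stack, _ = simulate_stack([shell_cell], iso_grid)
    return mask, truth, stack


def digitized_ball(radius_um: float, grid: GridSpec, center=None) -> np.ndarray:
    """Boolean ball mask via the dead-cell (solid) rasterization path."""
    if center is None:
        center = tuple(e / 2 for e in grid.extent_um)
    mask, _ = rasterize_cell(
        CellSpec(
            center=center,
            outer_radius=radius_um,
            wall_thickness=min(0.3, radius_um / 2),
            dead=True,
        ),
        grid,
    )
    return mask


@pytest.fixture
def ball_factory():
    return digitized_ball


def make_grid(values, spacing=(0.1, 0.1, 0.1)) -> VoxelGrid:
    return VoxelGrid(np.asarray(values, dtype=float), spacing)


@pytest.fixture
def grid_factory():
    return make_grid
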