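import numpy as np
import pytest

from contourvar.core import DoseGrid, StructureMask, VoxelGrid


def box_mask(grid: VoxelGrid, lo, hi, label="box") -> StructureMask:
    """Axis-aligned box of occupied voxels, [lo, hi) in index space."""
    occ = np.zeros(grid.shape, dtype=bool)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return StructureMask(grid=grid, occupancy=occ, label=label)


def random_mask(grid: VoxelGrid, rng, p=0.3, label="rand") -> StructureMask:
    occ = rng.random(grid.shape) < p
    return StructureMask(grid=grid, occupancy=occ, label=label)


def uniform_dose(grid: VoxelGrid, value_gy: float) -> DoseGrid:
    return DoseGrid(grid=grid, dose_gy=np.full(grid.shape, float(value_gy)))


@pytest.fixture
def iso_grid():
    return VoxelGrid((20, 20, 20), (1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid():
    return VoxelGrid((24, 24, 12), (1.0, 1.0, 2.5))


@pytest.fixture(scope="session")
def small_patient():
    """One simulated patient on a reduced grid, shared across tests."""
    from contourvar.synthetic import DoseModel, ObserverModel, simulate_patient

    grid = VoxelGrid((64, 64, 48), (2.0, 2.0, 2.5))
    observers = (
        ObserverModel("under", volume_bias_mm=-3.0, surface_noise_mm=0.8, shift_mm=0.4),
        ObserverModel("over", volume_bias_mm=+2.0, surface_noise_mm=0.8, shift_mm=0.4),
    )
    return simulate_patient(
        "p001", observers=observers, dose_model=DoseModel(), grid=grid, seed=7
    )
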