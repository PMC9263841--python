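"""Shared fixtures: tiny grids, hand-sized acquisitions, toy connectomes."""

import numpy as np
import pytest

from normconn import (AcquisitionMatrix, BinaryMask, Connectome, VoxelGrid)


@pytest.fixture
def tiny_grid():
    """A 4 x 3 x 2 grid (24 voxels) at 2 mm isotropic."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = (-4.0, -3.0, -2.0)
    return VoxelGrid((4, 3, 2), affine)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_acquisition(grid, acq_id, rng, n_volumes=20, voxel_indices=None):
    """Random full-coverage acquisition on ``grid`` (helper, not a fixture)."""
    if voxel_indices is None:
        voxel_indices = np.arange(grid.voxel_count)
    data = rng.standard_normal((len(voxel_indices), n_volumes))
    return AcquisitionMatrix(acq_id, grid, voxel_indices, data)


@pytest.fixture
def toy_connectome(tiny_grid, rng):
    """Ten random full-coverage acquisitions of 20 volumes each."""
    acqs = [make_acquisition(tiny_grid, f"acq{i}", rng) for i in range(10)]
    return Connectome(tiny_grid, acqs, name="toy")


@pytest.fixture
def seed_mask(tiny_grid):
    """A 3-voxel seed on the tiny grid."""
    return BinaryMask(tiny_grid, [0, 1, 5])
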