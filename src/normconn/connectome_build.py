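"""Build a connectome from preprocessed 4-D volumes and compute coverage.

Inputs are assumed already preprocessed and registered to a shared template
grid; this module only extracts voxel timeseries, collates acquisitions, and
derives the coverage mask (the voxels with usable signal in at least a
stated fraction of acquisitions).
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Sequence

import numpy as np

from .core import (AcquisitionMatrix, BinaryMask, Connectome, InvalidInputError,
                   VoxelGrid, is_effectively_constant, require_same_grid)

logger = logging.getLogger("normconn")


def extract_timeseries(volume_4d: np.ndarray, grid: VoxelGrid,
                       brain_mask: BinaryMask, acquisition_id: str) -> AcquisitionMatrix:
    """Voxel-by-time matrix of one acquisition, restricted to usable voxels.

    A voxel contributes a row iff it is (i) inside ``brain_mask``, (ii)
    all-finite across time, and (iii) of nonzero variance across time; this
    is the operational definition of "BOLD signal could be calculated".
    Voxel rows are sorted by ascending flat index (x-fastest).
    """
    require_same_grid(grid, brain_mask.grid, "volume and brain mask")
    volume_4d = np.asarray(volume_4d, dtype=float)
    if volume_4d.ndim != 4:
        raise InvalidInputError(f"expected a 4-D volume, got {volume_4d.ndim}-D")
    if volume_4d.shape[:3] != grid.dims:
        raise InvalidInputError(
            f"volume spatial shape {volume_4d.shape[:3]} != grid dims {grid.dims}")
    if volume_4d.shape[3] < 3:
        raise InvalidInputError("need at least 3 volumes")
    flat = volume_4d.reshape(grid.voxel_count, volume_4d.shape[3], order="F")
    candidates = brain_mask.members
    rows = flat[candidates]
    usable = np.isfinite(rows).all(axis=1) & ~is_effectively_constant(rows, axis=1)
    if not usable.any():
        raise InvalidInputError(
            f"acquisition {acquisition_id!r}: no in-mask voxel has usable signal")
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("acquisition %s: %d of %d in-mask voxels unusable",
                    acquisition_id, n_dropped, candidates.size)
    return AcquisitionMatrix(acquisition_id, grid, candidates[usable], rows[usable])


def assemble_connectome(matrices: Sequence[AcquisitionMatrix],
                        name: str = "connectome") -> Connectome:
    """Collate acquisitions into a single connectome, order-preserving.

    Acquisitions with differing volume counts are accepted (correlation is
    computed per acquisition), with a logged warning.
    """
    matrices = list(matrices)
    if not matrices:
        raise InvalidInputError("need at least one acquisition matrix")
    ts = {m.T for m in matrices}
    if len(ts) > 1:
        logger.warning("acquisitions have differing volume counts: %s", sorted(ts))
    return Connectome(matrices[0].grid, matrices, name=name)


def compute_coverage_mask(connectome: Connectome,
                          min_fraction: float = 0.8) -> BinaryMask:
    """Voxels with usable signal in at least ``min_fraction`` of acquisitions.

    The "at least" comparison is done on exact rationals (count * q >= n * p
    for min_fraction = p/q), so a voxel valid in exactly 80% of acquisitions
    is included without float-boundary ambiguity.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise InvalidInputError("min_fraction must lie in (0, 1]")
    counts = np.zeros(connectome.grid.voxel_count, dtype=np.int64)
    for acq in connectome:
        counts[acq.voxel_indices] += 1
    frac = Fraction(min_fraction).limit_denominator(10**6)
    n = connectome.n_acquisitions
    members = np.flatnonzero(counts * frac.denominator >= n * frac.numerator)
    return BinaryMask(connectome.grid, members)


def coverage_counts(connectome: Connectome) -> np.ndarray:
    """Per-voxel count of acquisitions in which the voxel is usable."""
    counts = np.zeros(connectome.grid.voxel_count, dtype=np.int64)
    for acq in connectome:
        counts[acq.voxel_indices] += 1
    return counts
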