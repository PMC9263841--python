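"""Seed-based group connectivity mapping.

The workflow: extract the mean BOLD timeseries of a seed region within each
acquisition, correlate it with every valid voxel's timeseries to get a
per-acquisition r-map, average r-maps across acquisitions into a group
mean-r map, and test the (Fisher-z transformed) r values against zero per
voxel to get a group t-map, which is thresholded and binarized.

Group maps carry per-voxel contribution counts so that signal dropout
(fewer contributing acquisitions) is explicit: a voxel's t uses df = n - 1
with its own n, and voxels with n < 2 are no-data rather than zero.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (AcquisitionMatrix, BinaryMask, Connectome, InvalidInputError,
                   R_CLIP_EPS, StatMap, is_effectively_constant, require_same_grid)

logger = logging.getLogger("normconn")


def seed_timeseries(acq: AcquisitionMatrix, seed: BinaryMask) -> np.ndarray:
    """Unweighted mean timeseries across the seed voxels valid in ``acq``.

    Raises if no seed voxel is valid in this acquisition; at group level use
    the group functions, which simply skip such acquisitions.
    """
    rows = acq.rows_for(seed)
    if rows.size == 0:
        raise InvalidInputError(
            f"acquisition {acq.acquisition_id!r}: no valid voxel in seed")
    return acq.data[rows].mean(axis=0)


def _rmap_from_series(acq: AcquisitionMatrix, series: np.ndarray) -> np.ndarray:
    """Pearson r of ``series`` against every valid voxel row, vectorized."""
    s = series - series.mean()
    s_norm = np.sqrt(s @ s)
    x = acq.data - acq.data.mean(axis=1, keepdims=True)
    x_norm = np.sqrt(np.einsum("ij,ij->i", x, x))
    r = (x @ s) / (x_norm * s_norm)
    # guard against floating-point overshoot just outside [-1, 1]
    return np.clip(r, -1.0, 1.0)


def acquisition_rmap(acq: AcquisitionMatrix, seed: BinaryMask) -> np.ndarray:
    """Per-voxel r between the seed mean series and each valid voxel.

    Returns one value per row of ``acq.data`` (aligned with
    ``acq.voxel_indices``).  A constant seed series is an error here; group
    functions skip such acquisitions with a warning.
    """
    series = seed_timeseries(acq, seed)
    if is_effectively_constant(series):
        raise InvalidInputError(
            f"acquisition {acq.acquisition_id!r}: seed mean series is constant")
    return _rmap_from_series(acq, series)


def _iter_contributing_rmaps(connectome: Connectome, seed: BinaryMask):
    """Yield (acq, rmap) for acquisitions with a usable, non-constant seed."""
    require_same_grid(connectome.grid, seed.grid, "connectome and seed")
    for acq in connectome:
        rows = acq.rows_for(seed)
        if rows.size == 0:
            logger.warning("acquisition %s skipped: no valid seed voxel",
                           acq.acquisition_id)
            continue
        series = acq.data[rows].mean(axis=0)
        if is_effectively_constant(series):
            logger.warning("acquisition %s skipped: constant seed series",
                           acq.acquisition_id)
            continue
        yield acq, _rmap_from_series(acq, series)


def group_rmap(connectome: Connectome, seed: BinaryMask) -> StatMap:
    """Group mean-r map: the average correlation coefficient per voxel.

    Per voxel, the unweighted mean of r over the acquisitions in which the
    voxel is valid and the seed contributes; raw r values are averaged
    (not Fisher-z back-transformed).  ``n_per_voxel`` records contribution
    counts; voxels no acquisition covers are no-data.
    """
    n_vox = connectome.grid.voxel_count
    r_sum = np.zeros(n_vox)
    n = np.zeros(n_vox, dtype=np.int64)
    contributed = 0
    for acq, r in _iter_contributing_rmaps(connectome, seed):
        r_sum[acq.voxel_indices] += r
        n[acq.voxel_indices] += 1
        contributed += 1
    if contributed == 0:
        raise InvalidInputError("no acquisition contributes to this seed map")
    values = np.full(n_vox, np.nan)
    has = n > 0
    values[has] = r_sum[has] / n[has]
    return StatMap(connectome.grid, values, "mean_r", n)


def group_tmap(connectome: Connectome, seed: BinaryMask,
               space: str = "fisher_z") -> StatMap:
    """Group t-map: one-sample t of per-acquisition r against 0, per voxel.

    ``space`` selects what is tested: ``"fisher_z"`` (default) applies the
    variance-stabilizing arctanh before the t-test; ``"raw_r"`` tests the
    correlation coefficients directly.  df = n - 1 varies per voxel with
    coverage.  Voxels with n < 2, or with zero variance across
    acquisitions, are no-data (the latter are counted in a log message).
    """
    if space not in ("fisher_z", "raw_r"):
        raise InvalidInputError("space must be 'fisher_z' or 'raw_r'")
    n_vox = connectome.grid.voxel_count
    v_sum = np.zeros(n_vox)
    v_sumsq = np.zeros(n_vox)
    n = np.zeros(n_vox, dtype=np.int64)
    contributed = 0
    for acq, r in _iter_contributing_rmaps(connectome, seed):
        if space == "fisher_z":
            v = np.arctanh(np.clip(r, -1.0 + R_CLIP_EPS, 1.0 - R_CLIP_EPS))
        else:
            v = r
        v_sum[acq.voxel_indices] += v
        v_sumsq[acq.voxel_indices] += v * v
        n[acq.voxel_indices] += 1
        contributed += 1
    if contributed == 0:
        raise InvalidInputError("no acquisition contributes to this seed map")

    values = np.full(n_vox, np.nan)
    enough = n >= 2
    nn = n[enough].astype(float)
    mean = v_sum[enough] / nn
    # unbiased variance from running sums; clamp tiny negatives from rounding
    var = np.maximum((v_sumsq[enough] - nn * mean**2) / (nn - 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / nn)
    degenerate = var == 0.0
    if degenerate.any():
        logger.info("t-map: %d voxels with zero variance across acquisitions "
                    "set to no-data", int(degenerate.sum()))
    t[degenerate] = np.nan
    values[enough] = t
    n_out = n.copy()
    n_out[~np.isfinite(values)] = 0
    return StatMap(connectome.grid, values, "t", n_out)


def threshold_binarize(stat_map: StatMap, threshold: float = 2.8,
                       direction: str = "greater") -> BinaryMask:
    """Binarize a t- (or z-) map at a strict threshold.

    ``direction="greater"`` keeps voxels with value > threshold (the default
    one-sided positive rule, with anticorrelation handled separately);
    ``"abs_greater"`` keeps |value| > threshold.  No-data voxels are never
    included, and a value exactly at the threshold is excluded.
    """
    if stat_map.kind not in ("t", "z"):
        raise InvalidInputError(f"can only threshold t or z maps, got {stat_map.kind!r}")
    if direction not in ("greater", "abs_greater"):
        raise InvalidInputError("direction must be 'greater' or 'abs_greater'")
    vals = stat_map.values
    with np.errstate(invalid="ignore"):
        if direction == "greater":
            sel = vals > threshold
        else:
            sel = np.abs(vals) > threshold
    sel &= np.isfinite(vals)
    return BinaryMask(stat_map.grid, np.flatnonzero(sel))
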