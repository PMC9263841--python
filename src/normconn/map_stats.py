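"""Validation statistics on maps and masks.

Dice similarity and containment quantify spatial agreement of binary masks;
``compare_connectomes`` runs the voxelwise two-connectome comparison: a
Welch two-sample t-test on per-acquisition Fisher-z connectivity values at
every jointly covered voxel, corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats as _stats

from .core import (BinaryMask, Connectome, InvalidInputError, R_CLIP_EPS,
                   StatMap, bh_fdr, require_same_grid)
from .seed_mapping import _iter_contributing_rmaps

logger = logging.getLogger("normconn")


def dice(x: BinaryMask, y: BinaryMask) -> float:
    """Dice similarity coefficient 2|X n Y| / (|X| + |Y|), in [0, 1].

    Symmetric in its arguments.  Undefined (an error) when both masks are
    empty.
    """
    require_same_grid(x.grid, y.grid, "masks")
    denom = x.cardinality + y.cardinality
    if denom == 0:
        raise InvalidInputError("Dice is undefined for two empty masks")
    inter = np.intersect1d(x.members, y.members, assume_unique=True).size
    return 2.0 * inter / denom


def containment(x: BinaryMask, y: BinaryMask) -> float:
    """Fraction of X contained within Y: |X n Y| / |X|, in [0, 1].

    Unlike Dice this is asymmetric — it measures how much of ``x`` lies
    inside ``y``, not the reverse.
    """
    require_same_grid(x.grid, y.grid, "masks")
    if x.cardinality == 0:
        raise InvalidInputError("containment is undefined for an empty X")
    inter = np.intersect1d(x.members, y.members, assume_unique=True).size
    return inter / x.cardinality


@dataclasses.dataclass(frozen=True)
class ConnectomeComparison:
    """Result of a voxelwise two-connectome comparison."""

    p_map: StatMap
    t_map: StatMap
    significant: BinaryMask
    n_significant: int
    n_tested: int


def _group_z_moments(connectome: Connectome, seed: BinaryMask):
    """Per-voxel (sum, sum-of-squares, n) of Fisher-z connectivity."""
    n_vox = connectome.grid.voxel_count
    z_sum = np.zeros(n_vox)
    z_sumsq = np.zeros(n_vox)
    n = np.zeros(n_vox, dtype=np.int64)
    contributed = 0
    for acq, r in _iter_contributing_rmaps(connectome, seed):
        z = np.arctanh(np.clip(r, -1.0 + R_CLIP_EPS, 1.0 - R_CLIP_EPS))
        z_sum[acq.voxel_indices] += z
        z_sumsq[acq.voxel_indices] += z * z
        n[acq.voxel_indices] += 1
        contributed += 1
    if contributed == 0:
        raise InvalidInputError("seed contributes in no acquisition")
    return z_sum, z_sumsq, n


def compare_connectomes(conn_a: Connectome, conn_b: Connectome, seed: BinaryMask,
                        q: float = 0.05,
                        restrict: BinaryMask | None = None) -> ConnectomeComparison:
    """Voxelwise Welch test of seed connectivity between two connectomes.

    At every voxel covered by >= 2 acquisitions in each connectome (further
    intersected with ``restrict`` if given, e.g. a coverage mask), the
    per-acquisition Fisher-z connectivity values of group A and group B are
    compared with a two-sided Welch (unequal-variance) t-test; the p-values
    are corrected across all tested voxels with Benjamini-Hochberg FDR at
    level ``q``.  Swapping the groups flips t-signs but preserves p-values
    and the significant set.
    """
    require_same_grid(conn_a.grid, conn_b.grid, "connectomes")
    require_same_grid(conn_a.grid, seed.grid, "connectome and seed")
    sum_a, sumsq_a, n_a = _group_z_moments(conn_a, seed)
    sum_b, sumsq_b, n_b = _group_z_moments(conn_b, seed)

    testable = (n_a >= 2) & (n_b >= 2)
    if restrict is not None:
        require_same_grid(conn_a.grid, restrict.grid, "connectome and restrict mask")
        in_restrict = np.zeros(conn_a.grid.voxel_count, dtype=bool)
        in_restrict[restrict.members] = True
        testable &= in_restrict
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        raise InvalidInputError("no voxel is testable in both connectomes")

    na = n_a[idx].astype(float)
    nb = n_b[idx].astype(float)
    mean_a = sum_a[idx] / na
    mean_b = sum_b[idx] / nb
    var_a = np.maximum((sumsq_a[idx] - na * mean_a**2) / (na - 1.0), 0.0)
    var_b = np.maximum((sumsq_b[idx] - nb * mean_b**2) / (nb - 1.0), 0.0)
    se2 = var_a / na + var_b / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
        # Welch-Satterthwaite degrees of freedom
        df = se2**2 / (var_a**2 / (na**2 * (na - 1.0)) +
                       var_b**2 / (nb**2 * (nb - 1.0)))
    ok = np.isfinite(t) & np.isfinite(df)
    if not ok.all():
        logger.info("comparison: %d voxels with degenerate variances dropped",
                    int((~ok).sum()))
        idx, t, df = idx[ok], t[ok], df[ok]
        if idx.size == 0:
            raise InvalidInputError("no voxel is testable in both connectomes")
    p = 2.0 * _stats.t.sf(np.abs(t), df)
    reject = bh_fdr(p, q)

    n_vox = conn_a.grid.voxel_count
    p_values = np.full(n_vox, np.nan)
    p_values[idx] = p
    t_values = np.full(n_vox, np.nan)
    t_values[idx] = t
    n_joint = np.zeros(n_vox, dtype=np.int64)
    n_joint[idx] = n_a[idx] + n_b[idx]
    p_map = StatMap(conn_a.grid, p_values, "p", n_joint)
    t_map = StatMap(conn_a.grid, t_values, "t", n_joint)
    significant = BinaryMask(conn_a.grid, idx[reject])
    return ConnectomeComparison(p_map=p_map, t_map=t_map, significant=significant,
                                n_significant=significant.cardinality,
                                n_tested=int(idx.size))
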