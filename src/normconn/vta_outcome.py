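"""Clinical-outcome models from stimulation-volume connectivity.

Each patient's volume of tissue activated (VTA, the modeled stimulation
region around the DBS electrode; bilateral volumes form one seed mask) is
used as a seed in the normative connectome, and the mean connectivity of
that seed map over a motor region of interest is the predictor of the
patient's clinical outcome (e.g. % UPDRS-III change) in ordinary
least-squares linear models — one per ROI, plus a combined model over all
ROIs.

The reported R is the Pearson correlation of in-sample predicted vs actual
outcome.  For OLS with an intercept this equals the model's multiple
correlation coefficient, so the single-predictor p-value of that
correlation coincides with the slope's p-value.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats

from .core import (BinaryMask, Connectome, InvalidInputError, require_same_grid)
from .seed_mapping import group_rmap

logger = logging.getLogger("normconn")


@dataclasses.dataclass(frozen=True)
class OutcomeRecord:
    """One patient: a bilateral VTA seed mask and a clinical outcome."""

    patient_id: str
    vta: BinaryMask
    outcome: float

    def __post_init__(self) -> None:
        if self.vta.cardinality == 0:
            raise InvalidInputError(f"patient {self.patient_id!r}: empty VTA mask")
        if not np.isfinite(self.outcome):
            raise InvalidInputError(f"patient {self.patient_id!r}: non-finite outcome")


@dataclasses.dataclass(frozen=True)
class OutcomeModelResult:
    """A fitted connectivity-outcome linear model.

    ``R`` is Pearson(predicted, actual) on the in-sample fitted values, with
    ``p_value`` the two-sided test of that correlation.  ``slope_se`` holds
    one standard error per ROI slope, aligned with ``roi_labels``.
    """

    roi_labels: tuple[str, ...]
    intercept: float
    slopes: np.ndarray
    slope_se: np.ndarray
    predictions: np.ndarray
    R: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.R <= 1.0:
            raise InvalidInputError("R must lie in [-1, 1]")
        if len(self.predictions) != self.n:
            raise InvalidInputError("one prediction per patient required")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": self.roi_labels,
            "slope": self.slopes,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "R": self.R,
            "p_value": self.p_value,
            "n": self.n,
        })


def vta_roi_connectivity(connectome: Connectome, vta: BinaryMask,
                         roi: BinaryMask, method: str = "rmap") -> float:
    """Average connectivity between a VTA seed and an ROI.

    ``method="rmap"`` (default): the mean over ROI voxels (with at least one
    contributing acquisition) of the VTA-seeded group mean-r map — the same
    seed-map workflow used everywhere else.  ``method="pairwise"``: the mean
    over all (VTA voxel, ROI voxel) Pearson correlations within each
    acquisition, averaged across acquisitions; provided as a cross-check for
    the ambiguity between "correlation of region means" and "mean of
    voxel-pair correlations".
    """
    require_same_grid(connectome.grid, vta.grid, "connectome and VTA")
    require_same_grid(connectome.grid, roi.grid, "connectome and ROI")
    if method == "rmap":
        rmap = group_rmap(connectome, vta)
        roi_vals = rmap.values[roi.members]
        roi_vals = roi_vals[np.isfinite(roi_vals)]
        if roi_vals.size == 0:
            raise InvalidInputError("ROI has no voxel with data in the VTA seed map")
        return float(roi_vals.mean())
    if method == "pairwise":
        per_acq = []
        for acq in connectome:
            vta_rows = acq.rows_for(vta)
            roi_rows = acq.rows_for(roi)
            if vta_rows.size == 0 or roi_rows.size == 0:
                continue
            a = acq.data[vta_rows]
            b = acq.data[roi_rows]
            a = (a - a.mean(axis=1, keepdims=True))
            b = (b - b.mean(axis=1, keepdims=True))
            a /= np.linalg.norm(a, axis=1, keepdims=True)
            b /= np.linalg.norm(b, axis=1, keepdims=True)
            per_acq.append(float((a @ b.T).mean()))
        if not per_acq:
            raise InvalidInputError("no acquisition covers both VTA and ROI")
        return float(np.mean(per_acq))
    raise InvalidInputError("method must be 'rmap' or 'pairwise'")


def _connectivity_matrix(records: Sequence[OutcomeRecord], connectome: Connectome,
                         rois: Sequence[BinaryMask]) -> np.ndarray:
    return np.array([[vta_roi_connectivity(connectome, rec.vta, roi)
                      for roi in rois] for rec in records])


def _collinear_labels(design: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Labels of predictor columns lying in the span of earlier columns."""
    bad = []
    cols = [np.ones(design.shape[0])]  # intercept
    for j, label in enumerate(labels):
        basis = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(basis, design[:, j], rcond=None)
        resid = design[:, j] - basis @ coef
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(design[:, j]), 1.0):
            bad.append(label)
        else:
            cols.append(design[:, j])
    return bad


def fit_outcome_model(records: Sequence[OutcomeRecord], connectome: Connectome,
                      rois: Sequence[BinaryMask],
                      roi_labels: Sequence[str] | None = None,
                      leave_one_out: bool = False,
                      connectivity: np.ndarray | None = None) -> OutcomeModelResult:
    """OLS of outcome on VTA-ROI connectivity for one or more ROIs.

    Predictions are in-sample fitted values by default; with
    ``leave_one_out`` each patient's prediction comes from a model fitted on
    the other n-1 patients.  Rank-deficient designs raise an error naming
    the collinear ROIs.

    ``connectivity`` may supply the (n_patients, n_rois) predictor matrix
    precomputed with :func:`vta_roi_connectivity` on the same connectome and
    masks (its entries are deterministic), to avoid recomputing every seed
    map when refitting many cohorts drawn on one connectome.
    """
    records = list(records)
    rois = list(rois)
    if roi_labels is None:
        roi_labels = [f"roi{j}" for j in range(len(rois))]
    if len(roi_labels) != len(rois):
        raise InvalidInputError("one label per ROI required")
    k = len(rois)
    n = len(records)
    if k == 0:
        raise InvalidInputError("need at least one ROI")
    if n < max(3, k + 2):
        raise InvalidInputError(f"need at least {max(3, k + 2)} patients for {k} ROIs")

    if connectivity is None:
        conn = _connectivity_matrix(records, connectome, rois)
    else:
        conn = np.asarray(connectivity, dtype=float)
        if conn.shape != (n, k):
            raise InvalidInputError(f"connectivity must have shape ({n}, {k})")
    outcomes = np.array([rec.outcome for rec in records])
    if np.any(conn.std(axis=0) == 0.0):
        const = [roi_labels[j] for j in range(k) if conn[:, j].std() == 0.0]
        raise InvalidInputError(f"constant connectivity predictor for ROI(s): {const}")
    design = sm.add_constant(conn, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_labels(conn, roi_labels)
        raise InvalidInputError(f"collinear ROI predictors: {bad}")

    fit = sm.OLS(outcomes, design).fit()
    if leave_one_out:
        predictions = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            f_i = sm.OLS(outcomes[keep], design[keep]).fit()
            predictions[i] = float(design[i] @ f_i.params)
    else:
        predictions = np.asarray(fit.fittedvalues)

    if np.std(predictions) == 0.0:
        r_val, p_val = 0.0, 1.0
    else:
        res = _stats.pearsonr(predictions, outcomes)
        r_val, p_val = float(res.statistic), float(res.pvalue)
    return OutcomeModelResult(
        roi_labels=tuple(roi_labels),
        intercept=float(fit.params[0]),
        slopes=np.asarray(fit.params[1:]),
        slope_se=np.asarray(fit.bse[1:]),
        predictions=predictions,
        R=r_val,
        p_value=p_val,
        n=n,
    )


def fit_single_roi_model(records: Sequence[OutcomeRecord], connectome: Connectome,
                         roi: BinaryMask, roi_label: str = "roi",
                         leave_one_out: bool = False,
                         connectivity: np.ndarray | None = None) -> OutcomeModelResult:
    """Single-ROI linear model: outcome ~ intercept + connectivity."""
    if connectivity is not None:
        connectivity = np.asarray(connectivity, dtype=float).reshape(-1, 1)
    return fit_outcome_model(records, connectome, [roi], [roi_label],
                             leave_one_out=leave_one_out,
                             connectivity=connectivity)


def fit_combined_model(records: Sequence[OutcomeRecord], connectome: Connectome,
                       rois: Sequence[BinaryMask],
                       roi_labels: Sequence[str] | None = None,
                       leave_one_out: bool = False,
                       connectivity: np.ndarray | None = None) -> OutcomeModelResult:
    """Combined linear model over all ROIs' connectivity values."""
    return fit_outcome_model(records, connectome, rois, roi_labels,
                             leave_one_out=leave_one_out,
                             connectivity=connectivity)
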