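"""Scalar injury metrics and their univariate logistic classifiers.

Four metrics are computed per impact case:

* **BrIC** — root-sum-square of the per-axis peak angular-velocity magnitude
  over model-specific critical velocities (30.4 / 35.6 / 23.5 rad/s for the
  head model whose strain fields this pipeline consumes);
* **CSDM-WB / CSDM-CC** — the volume fraction of the whole brain / corpus
  callosum whose peak maximum principal strain exceeds a threshold (0.2);
* **Peak-CC** — the maximum fiber strain over the corpus callosum.

Each metric is turned into a probabilistic classifier by maximum-likelihood
univariate logistic regression, with a guard that detects complete
separation and falls back to a small ridge penalty instead of diverging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression

from .data import Dataset, StrainCase
from .grid import ROI_LABELS, VolumeGrid

__all__ = [
    "CriticalVelocities",
    "WHIM_CRITICAL_VELOCITIES",
    "LogisticModel",
    "compute_bric",
    "compute_csdm",
    "compute_peak_roi",
    "fit_univariate_logistic",
    "predict_logistic",
    "metric_table",
    "CSDM_THRESHOLD",
]

CSDM_THRESHOLD = 0.2


@dataclass(frozen=True)
class CriticalVelocities:
    """Per-axis critical angular velocities for BrIC, rad/s."""

    wxc: float
    wyc: float
    wzc: float

    def __post_init__(self):
        if min(self.wxc, self.wyc, self.wzc) <= 0:
            raise ValueError("critical velocities must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.wxc, self.wyc, self.wzc], dtype=float)


WHIM_CRITICAL_VELOCITIES = CriticalVelocities(30.4, 35.6, 23.5)


@dataclass
class LogisticModel:
    """Univariate logistic classifier p(concussion) = expit(b0 + b1 * x)."""

    intercept: float
    slope: float
    metric_name: str = ""
    separated: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("logistic coefficients must be finite")


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #
def compute_bric(
    peak_ang_vel, crit: CriticalVelocities = WHIM_CRITICAL_VELOCITIES
) -> float:
    """Brain injury criterion: sqrt(sum_i (w_i / w_ic)^2).

    ``peak_ang_vel`` holds the per-axis peak angular-velocity magnitudes in
    rad/s (non-negative by convention).
    """
    w = np.asarray(peak_ang_vel, dtype=float).reshape(3)
    if np.any(w < 0):
        raise ValueError("peak angular-velocity components must be >= 0")
    return float(np.sqrt(np.sum((w / crit.as_array()) ** 2)))


def compute_csdm(
    case: StrainCase, region_mask: np.ndarray, threshold: float = CSDM_THRESHOLD
) -> float:
    """Cumulative strain damage measure over a region.

    Voxel-count-weighted fraction of the region whose MPS strictly exceeds
    ``threshold`` (strict inequality, fixed convention).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != case.mps.shape:
        raise ValueError("region mask shape does not match the case's volumes")
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("CSDM region is empty")
    return float(np.count_nonzero(case.mps[region_mask] > threshold) / n)


def compute_peak_roi(case: StrainCase, grid: VolumeGrid, roi_label=ROI_LABELS["CC"]) -> float:
    """Maximum fiber strain over one ROI (Peak-CC for the corpus callosum)."""
    mask = grid.roi_mask(roi_label)  # raises on unknown/empty label
    return float(case.fiber_strain[mask].max())


# --------------------------------------------------------------------------- #
# logistic regression
# --------------------------------------------------------------------------- #
def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: some threshold on x splits the classes exactly."""
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x0.max() < x1.min() or x1.max() < x0.min())


def fit_univariate_logistic(
    metric_values,
    labels,
    metric_name: str = "",
    ridge: float = 1e-2,
) -> LogisticModel:
    """Maximum-likelihood univariate logistic regression with separation guard.

    Degenerate inputs are handled explicitly: a zero-variance metric yields
    the intercept-only model (slope 0, fitted probability = prevalence);
    complete separation is flagged and fitted with a small ridge penalty
    (``ridge`` = 1/C) so the coefficients stay finite.
    """
    x = np.asarray(metric_values, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if x.shape != y.shape:
        raise ValueError("metric_values and labels must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if set(classes.tolist()) != {0, 1} or counts.min() < 2:
        raise ValueError("need at least 2 cases in each of the two classes")

    if np.ptp(x) == 0:  # zero-variance metric -> intercept-only ML solution
        return LogisticModel(
            intercept=float(logit(y.mean())), slope=0.0, metric_name=metric_name
        )

    def _ridge_fallback():
        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
        clf.fit(x[:, None], y)
        return LogisticModel(
            intercept=float(clf.intercept_[0]),
            slope=float(clf.coef_[0, 0]),
            metric_name=metric_name,
            separated=True,
        )

    if _is_separated(x, y):
        return _ridge_fallback()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        params = np.asarray(res.params, dtype=float)
    except Exception:
        # quasi-separation or a near-degenerate metric (e.g. mostly zeros)
        # makes the Newton step singular; the penalized fit stays finite
        params = None
    if params is None or not np.all(np.isfinite(params)):
        return _ridge_fallback()
    return LogisticModel(
        intercept=float(params[0]), slope=float(params[1]),
        metric_name=metric_name,
    )


def predict_logistic(model: LogisticModel, metric_value) -> np.ndarray:
    """Concussion probability expit(b0 + b1*x); decision rule p >= 0.5."""
    if model is None:
        raise ValueError("model is not fitted")
    x = np.asarray(metric_value, dtype=float)
    return expit(model.intercept + model.slope * x)


# --------------------------------------------------------------------------- #
# per-dataset table
# --------------------------------------------------------------------------- #
def metric_table(
    dataset: Dataset,
    crit: CriticalVelocities = WHIM_CRITICAL_VELOCITIES,
    csdm_threshold: float = CSDM_THRESHOLD,
) -> pd.DataFrame:
    """All four scalar metrics for every case (exportable as CSV)."""
    grid = dataset.grid
    cc_mask = grid.roi_mask("CC")
    rows = []
    for c in dataset.cases:
        rows.append(
            {
                "case_id": c.case_id,
                "BrIC": compute_bric(c.peak_ang_vel, crit),
                "CSDM_WB": compute_csdm(c, grid.brain_mask, csdm_threshold),
                "CSDM_CC": compute_csdm(c, cc_mask, csdm_threshold),
                "Peak_CC": compute_peak_roi(c, grid, ROI_LABELS["CC"]),
                "label": c.label,
            }
        )
    return pd.DataFrame(rows)
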