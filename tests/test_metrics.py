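"""Scalar injury metrics and univariate logistic classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from strainclass.data import StrainCase
from strainclass.metrics import (WHIM_CRITICAL_VELOCITIES, CriticalVelocities,
                                 compute_bric, compute_csdm, compute_peak_roi,
                                 fit_univariate_logistic, metric_table,
                                 predict_logistic)


def _case_with_mps(grid, mps, fiber=None, label=1):
    if fiber is None:
        fiber = np.where(grid.wm_mask, mps, 0.0)
    return StrainCase(case_id="t", fiber_strain=fiber, mps=mps,
                      peak_ang_vel=[1.0, 1.0, 1.0], label=label)


# --------------------------------------------------------------------------- #
# BrIC
# --------------------------------------------------------------------------- #
def test_bric_single_axis_at_critical():
    assert compute_bric([30.4, 0, 0]) == pytest.approx(1.0)


def test_bric_zero():
    assert compute_bric([0, 0, 0]) == 0.0


def test_bric_all_axes_critical():
    val = compute_bric([30.4, 35.6, 23.5])
    assert val == pytest.approx(np.sqrt(3.0), rel=1e-12)


def test_bric_negative_component():
    with pytest.raises(ValueError):
        compute_bric([-1.0, 0, 0])


def test_bric_invalid_critical_velocities():
    with pytest.raises(ValueError):
        CriticalVelocities(0.0, 35.6, 23.5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    w=st.tuples(*[st.floats(0, 100) for _ in range(3)]),
    c=st.floats(0, 10),
)
def test_bric_positive_homogeneity(w, c):
    w = np.array(w)
    assert compute_bric(c * w) == pytest.approx(c * compute_bric(w), abs=1e-9)


# --------------------------------------------------------------------------- #
# CSDM
# --------------------------------------------------------------------------- #
def test_csdm_all_above(tiny_dataset):
    grid = tiny_dataset.grid
    mps = np.where(grid.brain_mask, 0.3, 0.0)
    assert compute_csdm(_case_with_mps(grid, mps), grid.brain_mask, 0.2) == 1.0


def test_csdm_all_below(tiny_dataset):
    grid = tiny_dataset.grid
    mps = np.where(grid.brain_mask, 0.1, 0.0)
    assert compute_csdm(_case_with_mps(grid, mps), grid.brain_mask, 0.2) == 0.0


def test_csdm_half(tiny_dataset):
    """Half the region above threshold -> volume fraction 0.5."""
    grid = tiny_dataset.grid
    idx = np.argwhere(grid.brain_mask)
    mps = np.zeros(grid.shape)
    half = len(idx) // 2
    # make region size even so the fraction is exactly one half
    region = np.zeros(grid.shape, dtype=bool)
    region[tuple(idx[: 2 * half].T)] = True
    mps[tuple(idx[:half].T)] = 0.3
    mps[tuple(idx[half : 2 * half].T)] = 0.1
    case = _case_with_mps(grid, np.where(grid.brain_mask, mps, 0.0))
    assert compute_csdm(case, region, 0.2) == pytest.approx(0.5)


def test_csdm_monotone_in_threshold(tiny_dataset):
    grid = tiny_dataset.grid
    case = tiny_dataset.cases[0]
    vals = [compute_csdm(case, grid.brain_mask, t) for t in (0.0, 0.05, 0.1, 0.2, 0.4)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    # strictly positive region: every voxel exceeds threshold 0 (strict >)
    mps = np.where(grid.brain_mask, 0.01, 0.0)
    assert compute_csdm(_case_with_mps(grid, mps), grid.brain_mask, 0.0) == 1.0


def test_csdm_empty_region(tiny_dataset):
    grid = tiny_dataset.grid
    with pytest.raises(ValueError, match="empty"):
        compute_csdm(tiny_dataset.cases[0], np.zeros(grid.shape, dtype=bool))


# --------------------------------------------------------------------------- #
# Peak-ROI
# --------------------------------------------------------------------------- #
def test_peak_roi_zero_case(tiny_dataset):
    grid = tiny_dataset.grid
    case = _case_with_mps(grid, np.zeros(grid.shape))
    assert compute_peak_roi(case, grid, 1) == 0.0


def test_peak_roi_single_voxel(tiny_dataset):
    grid = tiny_dataset.grid
    fiber = np.zeros(grid.shape)
    cc_voxel = np.argwhere(grid.roi_labels == 1)[0]
    fiber[tuple(cc_voxel)] = 0.4
    case = StrainCase(case_id="t", fiber_strain=fiber,
                      mps=np.where(grid.brain_mask, 0.5, 0.0),
                      peak_ang_vel=[0, 0, 0], label=0)
    assert compute_peak_roi(case, grid, 1) == pytest.approx(0.4)


def test_peak_roi_matches_exhaustive_scan(tiny_dataset):
    grid = tiny_dataset.grid
    case = tiny_dataset.cases[2]
    brute = max(case.fiber_strain[tuple(v)] for v in np.argwhere(grid.roi_labels == 1))
    assert compute_peak_roi(case, grid, 1) == pytest.approx(brute)


def test_peak_roi_unknown_label(tiny_dataset):
    with pytest.raises(Exception):
        compute_peak_roi(tiny_dataset.cases[0], tiny_dataset.grid, 42)


def test_peak_exceeds_csdm_threshold_when_positive(tiny_dataset):
    """If CSDM(region, t) > 0 then the peak over the region exceeds t."""
    grid = tiny_dataset.grid
    cc = grid.roi_mask(1)
    for case in tiny_dataset.cases[:5]:
        t = 0.05
        csdm_fiber = np.count_nonzero(case.fiber_strain[cc] > t) / cc.sum()
        if csdm_fiber > 0:
            assert compute_peak_roi(case, grid, 1) > t


# --------------------------------------------------------------------------- #
# univariate logistic regression
# --------------------------------------------------------------------------- #
def test_logistic_zero_variance_metric():
    y = np.array([0] * 6 + [1] * 4)
    model = fit_univariate_logistic(np.full(10, 3.3), y)
    assert model.slope == 0.0
    np.testing.assert_allclose(predict_logistic(model, np.full(10, 3.3)),
                               np.full(10, 0.4), rtol=1e-9)


def test_logistic_parameter_recovery(rng):
    """ML fit recovers a known logistic law within 10% at n=2000."""
    n = 2000
    x = rng.normal(size=n)
    true_b0, true_b1 = -0.4, 1.7
    y = (rng.random(n) < expit(true_b0 + true_b1 * x)).astype(int)
    model = fit_univariate_logistic(x, y)
    assert model.slope == pytest.approx(true_b1, rel=0.10)
    assert model.intercept == pytest.approx(true_b0, abs=0.25)
    assert not model.separated


def test_logistic_separation_flag():
    x = np.array([0.0, 0.1, 0.2, 0.3, 1.0, 1.1, 1.2, 1.3])
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    model = fit_univariate_logistic(x, y)
    assert model.separated
    assert np.isfinite(model.slope) and model.slope > 0


def test_logistic_single_class_error():
    with pytest.raises(ValueError):
        fit_univariate_logistic(np.arange(6.0), np.ones(6, dtype=int))


def test_predict_logistic_closed_form():
    from strainclass.metrics import LogisticModel

    model = LogisticModel(intercept=-1.0, slope=2.0)
    # logit zero at x = -b0/b1 -> probability 0.5
    assert predict_logistic(model, 0.5) == pytest.approx(0.5)
    grid = np.linspace(-4, 4, 33)
    np.testing.assert_allclose(predict_logistic(model, grid),
                               1.0 / (1.0 + np.exp(-(-1.0 + 2.0 * grid))))
    # positive slope -> strictly increasing
    p = predict_logistic(model, grid)
    assert np.all(np.diff(p) > 0)


def test_metric_table_columns(tiny_dataset):
    table = metric_table(tiny_dataset)
    assert list(table.columns) == ["case_id", "BrIC", "CSDM_WB", "CSDM_CC",
                                   "Peak_CC", "label"]
    assert len(table) == len(tiny_dataset)
    assert (table["BrIC"] >= 0).all()
    assert table["CSDM_WB"].between(0, 1).all()
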