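"""F-score and RF-voting feature selection, and selection probability maps."""

import numpy as np
import pytest

from strainclass._utils import derive_seed
from strainclass.selection import (SelectionMask, fscore_rank, rf_vote_select,
                                   select_top_fraction,
                                   selection_probability_map)
from strainclass.synthetic import ground_truth


def _fscore_brute(X, y):
    """Direct, per-voxel evaluation of the F-score formula."""
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        x1, x0 = x[y == 1], x[y == 0]
        num = (x1.mean() - x.mean()) ** 2 + (x0.mean() - x.mean()) ** 2
        den = x1.var(ddof=1) + x0.var(ddof=1)
        out[j] = num / den if den > 0 else (0.0 if num == 0 else np.inf)
    return out


def test_fscore_constant_voxel_scores_zero(rng):
    X = rng.random((10, 5))
    X[:, 2] = 0.7
    y = np.array([0, 1] * 5)
    scores = fscore_rank(X, y)
    assert scores[2] == 0.0
    assert np.all(scores >= 0) and np.all(np.isfinite(scores))


def test_fscore_matches_brute_force(rng):
    X = rng.random((4, 2))
    y = np.array([0, 0, 1, 1])
    np.testing.assert_allclose(fscore_rank(X, y), _fscore_brute(X, y))
    X2 = rng.random((12, 30))
    y2 = (rng.random(12) < 0.5).astype(int)
    if 2 <= y2.sum() <= 10:
        np.testing.assert_allclose(fscore_rank(X2, y2), _fscore_brute(X2, y2))


def test_fscore_case_order_invariance(rng):
    X = rng.random((12, 8))
    y = np.array([0, 1] * 6)
    perm = rng.permutation(12)
    np.testing.assert_allclose(fscore_rank(X, y), fscore_rank(X[perm], y[perm]))


def test_fscore_between_class_constant_gets_max():
    X = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
    y = np.array([0, 0, 1, 1])
    scores = fscore_rank(X, y)
    assert scores[0] == scores.max()


def test_fscore_single_class_error():
    with pytest.raises(ValueError):
        fscore_rank(np.random.rand(4, 3), np.zeros(4, dtype=int))


# --------------------------------------------------------------------------- #
def test_select_top_fraction_all():
    mask = select_top_fraction(np.arange(10.0), 1.0)
    assert len(mask) == 10


def test_select_top_one_percent_of_paper_wm_count(rng):
    scores = rng.random(64272)
    mask = select_top_fraction(scores, 0.01)
    assert len(mask) == 643


def test_select_top_fraction_tie_rule():
    mask = select_top_fraction(np.ones(10), 0.5)
    np.testing.assert_array_equal(mask.indices, np.arange(5))


def test_select_top_fraction_invalid():
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            select_top_fraction(np.arange(4.0), bad)


# --------------------------------------------------------------------------- #
def test_rf_vote_single_run_collapses_to_importance_ranking(rng):
    from sklearn.ensemble import RandomForestClassifier

    X = rng.random((20, 100))
    y = np.array([0, 1] * 10)
    mask = rf_vote_select(X, y, n_runs=1, per_run_fraction=0.05,
                          final_fraction=0.05, seed=9, n_trees=10, max_depth=4)
    rf = RandomForestClassifier(n_estimators=10, max_depth=4,
                                random_state=derive_seed(9, "rfvote", 0), n_jobs=1)
    rf.fit(X, y)
    expect = select_top_fraction(rf.feature_importances_, 0.05)
    np.testing.assert_array_equal(mask.indices, expect.indices)


def test_rf_vote_mask_size_contract(rng):
    X = rng.random((16, 200))
    y = np.array([0, 1] * 8)
    m1 = rf_vote_select(X, y, n_runs=3, seed=1, n_trees=5, max_depth=3)
    m2 = rf_vote_select(X, y, n_runs=3, seed=2, n_trees=5, max_depth=3)
    assert len(m1) == len(m2) == 2  # round(0.01 * 200)
    # determinism given the seed
    m3 = rf_vote_select(X, y, n_runs=3, seed=1, n_trees=5, max_depth=3)
    np.testing.assert_array_equal(m1.indices, m3.indices)


def test_rf_vote_recovers_planted_signal(desk_config, desk_dataset, desk_features):
    """Voting selection concentrates on the planted discriminative ROIs."""
    gt = ground_truth(desk_config, desk_dataset)
    planted = set(gt["planted_feature_indices"].tolist())
    mask = rf_vote_select(desk_features, desk_dataset.labels, n_runs=25,
                          seed=3, n_trees=25, max_depth=8)
    hit = np.mean([i in planted for i in mask.indices])
    chance = len(planted) / desk_dataset.grid.n_wm
    assert hit >= 0.5
    assert hit > 5 * chance


def test_rf_vote_null_under_label_permutation(desk_dataset, desk_features, desk_config):
    """Permuted labels leave planted-ROI enrichment at chance level."""
    gt = ground_truth(desk_config, desk_dataset)
    planted = set(gt["planted_feature_indices"].tolist())
    chance = len(planted) / desk_dataset.grid.n_wm
    rng = np.random.default_rng(11)
    hits = []
    for trial in range(20):
        y_perm = rng.permutation(desk_dataset.labels)
        mask = rf_vote_select(desk_features, y_perm, n_runs=5, seed=trial,
                              n_trees=10, max_depth=4)
        hits.append(np.mean([i in planted for i in mask.indices]))
    # binomial 95% band around the chance rate over the pooled selections
    pooled_n = 20 * len(mask)
    se = np.sqrt(chance * (1 - chance) / pooled_n)
    assert abs(np.mean(hits) - chance) < 4 * se + 0.02


def test_rf_vote_degenerate_labels(rng):
    with pytest.raises(ValueError):
        rf_vote_select(rng.random((6, 10)), np.zeros(6, dtype=int), n_runs=1)


# --------------------------------------------------------------------------- #
def test_probability_map_frequencies(tiny_dataset):
    grid = tiny_dataset.grid
    masks = [SelectionMask(indices=[0, 1], method="fscore", fold_id=k)
             for k in range(58)]
    for k in range(29):
        masks[k] = SelectionMask(indices=[0, 1, 5], method="fscore", fold_id=k)
    pmap = selection_probability_map(masks, grid)
    assert pmap.frequency[5] == pytest.approx(0.5)  # selected 29 of 58 folds
    assert pmap.frequency[0] == 1.0
    assert pmap.frequency[7] == 0.0
    counts = pmap.frequency * pmap.n_folds
    np.testing.assert_allclose(counts, np.round(counts))
    # threshold is strict: frequency exactly 0.5 is not shown at cutoff 0.5
    assert not pmap.threshold_mask(0.5)[5]
    assert pmap.threshold_mask(0.5)[0]


def test_probability_map_identical_masks_is_indicator(tiny_dataset):
    grid = tiny_dataset.grid
    mask = SelectionMask(indices=[2, 3, 4], method="rfvote")
    pmap = selection_probability_map([mask] * 5, grid)
    expect = np.zeros(grid.n_wm)
    expect[[2, 3, 4]] = 1.0
    np.testing.assert_array_equal(pmap.frequency, expect)


def test_probability_map_mixed_methods_error(tiny_dataset):
    masks = [SelectionMask(indices=[0], method="fscore"),
             SelectionMask(indices=[0], method="rfvote")]
    with pytest.raises(ValueError, match="mixed"):
        selection_probability_map(masks, tiny_dataset.grid)
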