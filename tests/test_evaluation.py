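"""Cross-validation, bootstrap, .632+ and randomized-label machinery."""

import numpy as np
import pytest

from strainclass.evaluation import (ScalarMetricConfig, assemble_report,
                                    bootstrap_run, confusion_metrics,
                                    dot632plus_error, loocv_run,
                                    randomized_label_test, roc_auc)


# --------------------------------------------------------------------------- #
# confusion metrics
# --------------------------------------------------------------------------- #
def test_confusion_all_correct():
    y = np.array([0, 1, 0, 1])
    m = confusion_metrics(y, y)
    assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1, 1, 1)


def test_confusion_study_scale_counts():
    """19/25 concussions and 30/33 non-injuries correct."""
    truth = np.array([1] * 25 + [0] * 33)
    pred = np.array([1] * 19 + [0] * 6 + [0] * 30 + [1] * 3)
    m = confusion_metrics(truth, pred)
    assert m["sensitivity"] == pytest.approx(0.760)
    assert m["specificity"] == pytest.approx(0.909, abs=5e-4)


def test_confusion_all_positive():
    truth = np.array([1, 1, 0, 0])
    m = confusion_metrics(truth, np.ones(4, dtype=int))
    assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0


def test_confusion_empty_error():
    with pytest.raises(ValueError):
        confusion_metrics([], [])


# --------------------------------------------------------------------------- #
# ROC / AUC
# --------------------------------------------------------------------------- #
def _auc_pairwise(scores, truth):
    """Exhaustive concordance over all positive x negative pairs, ties 1/2."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_separation():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])[0] == 1.0


def test_auc_constant_scores():
    assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])[0] == 0.5


def test_auc_matches_pairwise_oracle(rng):
    for trial in range(25):
        n = int(rng.integers(4, 21))
        truth = np.zeros(n, dtype=int)
        truth[: int(rng.integers(1, n))] = 1
        rng.shuffle(truth)
        if truth.sum() in (0, n):
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid to force ties
        auc, _, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(_auc_pairwise(scores, truth))


def test_auc_single_class_error():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# --------------------------------------------------------------------------- #
# .632+
# --------------------------------------------------------------------------- #
def _balanced_setup():
    labels = np.array([1] * 5 + [0] * 5)
    preds = np.array([1] * 5 + [0] * 5)  # q = 0.5 -> gamma = 0.5
    return labels, preds


def test_dot632plus_equal_errors_returns_train():
    labels, preds = _balanced_setup()
    assert dot632plus_error(0.2, 0.2, labels, preds) == pytest.approx(0.2)


def test_dot632plus_worked_case():
    """err_train=0.1, err_oob=0.3, gamma=0.5 -> R=0.5, w=0.632/0.816."""
    labels, preds = _balanced_setup()
    val = dot632plus_error(0.1, 0.3, labels, preds)
    w = 0.632 / (1 - 0.368 * 0.5)
    assert val == pytest.approx((1 - w) * 0.1 + w * 0.3)
    assert val == pytest.approx(0.2549, abs=2e-4)


def test_dot632plus_limiting_case_w_equals_one():
    labels, preds = _balanced_setup()
    assert dot632plus_error(0.0, 0.5, labels, preds) == pytest.approx(0.5)


def test_dot632plus_within_bounds(rng):
    labels, preds = _balanced_setup()
    for _ in range(50):
        a, b = sorted(rng.random(2))
        v = dot632plus_error(a, b, labels, preds)
        bmax = min(b, 0.5)  # after the overfitting clamp at gamma
        assert min(a, bmax) - 1e-12 <= v <= max(a, bmax) + 1e-12


def test_dot632plus_class_relabel_invariance(rng):
    labels = np.array([1] * 4 + [0] * 6)
    preds = (rng.random(10) < 0.5).astype(int)
    v1 = dot632plus_error(0.15, 0.35, labels, preds)
    v2 = dot632plus_error(0.15, 0.35, 1 - labels, 1 - preds)
    assert v1 == pytest.approx(v2)


def test_dot632plus_invalid_rates():
    labels, preds = _balanced_setup()
    with pytest.raises(ValueError):
        dot632plus_error(-0.1, 0.2, labels, preds)


# --------------------------------------------------------------------------- #
# LOOCV
# --------------------------------------------------------------------------- #
def test_loocv_record_count_and_training_aucs(tiny_dataset):
    values = tiny_dataset.kinematics().sum(axis=1)
    run = loocv_run(tiny_dataset, {"kin": ScalarMetricConfig("kin")},
                    features=values[:, None], seed=3)
    res = run.results["kin"]
    n = len(tiny_dataset)
    assert len(res.records) == n
    assert res.training_aucs.shape == (n,)
    assert all(r.predicted == (r.p1 >= 0.5) for r in res.records)
    s = res.training_auc_summary()
    assert s["worst"] <= s["mean"] <= s["best"]


def test_loocv_held_out_case_never_trains(tiny_dataset, rng):
    """Fold k's selection and trained model are independent of case k."""
    from strainclass.evaluation import _loocv_matrix
    from strainclass.classifiers import SVMConfig
    from strainclass.selection import SelectionConfig

    X = tiny_dataset.feature_matrix()
    y = tiny_dataset.labels
    sel = SelectionConfig(method="fscore", fraction=0.02)
    cfg = {"svm": SVMConfig()}
    k = 4
    run1 = _loocv_matrix(X, y, cfg, sel, seed=5)
    X2 = X.copy()
    X2[k] = rng.random(X.shape[1])  # perturb only the held-out case
    run2 = _loocv_matrix(X2, y, cfg, sel, seed=5)
    np.testing.assert_array_equal(run1.masks[k].indices, run2.masks[k].indices)
    # the model fitted in fold k is unchanged: identical training probabilities
    np.testing.assert_allclose(run1.results["svm"].fold_train_probs[k],
                               run2.results["svm"].fold_train_probs[k])
    assert run1.results["svm"].training_aucs[k] == run2.results["svm"].training_aucs[k]
    # only the held-out prediction for case k responds to the perturbation
    assert run1.results["svm"].records[k].p1 != run2.results["svm"].records[k].p1


def test_loocv_strong_metric_beats_chance(tiny_dataset, tiny_config):
    from strainclass.synthetic import ground_truth

    gt = ground_truth(tiny_config, tiny_dataset)
    m = tiny_dataset.feature_matrix()[:, gt["planted_feature_indices"]].mean(axis=1)
    run = loocv_run(tiny_dataset, {"planted": ScalarMetricConfig("planted")},
                    features=m[:, None], seed=1)
    assert run.results["planted"].metrics()["accuracy"] >= 0.8


def test_loocv_too_small():
    import strainclass.evaluation as ev

    with pytest.raises(ValueError):
        ev._loocv_matrix(np.random.rand(3, 2), np.array([0, 1, 1]),
                         {"m": ScalarMetricConfig("m")}, None, seed=0)


# --------------------------------------------------------------------------- #
# bootstrap
# --------------------------------------------------------------------------- #
def test_bootstrap_trial_count_and_determinism(tiny_dataset):
    values = tiny_dataset.kinematics().sum(axis=1)[:, None]
    out1 = bootstrap_run(tiny_dataset, ScalarMetricConfig("kin"), None,
                         n_boot=10, seed=4, features=values)
    out2 = bootstrap_run(tiny_dataset, ScalarMetricConfig("kin"), None,
                         n_boot=10, seed=4, features=values)
    assert len(out1["trials"]) == 10
    assert out1["trials"].equals(out2["trials"])
    assert 0 <= out1["err632plus"] <= 1


def test_bootstrap_constant_classifier_matches_prevalence():
    """A constant majority vote scores ~the majority prevalence out of bag.

    With a strongly imbalanced dataset the intercept-only logistic model is a
    constant majority-class vote in essentially every bootstrap bag, so the
    expected out-of-bag accuracy is the majority prevalence.
    """
    from strainclass.synthetic import GeneratorConfig, generate_dataset

    ds = generate_dataset(GeneratorConfig(grid_shape=(24, 24, 24), n_cases=16,
                                          n_concussion=3, seed=21))
    const = np.zeros((len(ds), 1))
    out = bootstrap_run(ds, ScalarMetricConfig("const"), None,
                        n_boot=40, seed=9, features=const)
    majority = max(ds.class_counts) / len(ds)
    assert out["summary"]["accuracy"]["mean"] == pytest.approx(majority, abs=0.08)


def test_bootstrap_requires_two_trials(tiny_dataset):
    with pytest.raises(ValueError):
        bootstrap_run(tiny_dataset, ScalarMetricConfig("x"), None, n_boot=1,
                      features=np.zeros((len(tiny_dataset), 1)))


# --------------------------------------------------------------------------- #
# randomized labels
# --------------------------------------------------------------------------- #
def test_randomized_label_null_and_positive_control(tiny_dataset, tiny_config):
    from strainclass.synthetic import ground_truth

    gt = ground_truth(tiny_config, tiny_dataset)
    m = tiny_dataset.feature_matrix()[:, gt["planted_feature_indices"]].mean(axis=1)
    configs = {"planted": ScalarMetricConfig("planted")}
    out = randomized_label_test(tiny_dataset, configs, n_trials=10, seed=2,
                                features=m[:, None])
    assert len(out["trials"]) == 10
    p_null = out["summary"]["planted"]["accuracy"]["p_vs_0.5"]
    assert p_null > 0.05 or out["summary"]["planted"]["accuracy"]["mean"] < 0.62
    # positive control: the unpermuted metric is far above chance
    run = loocv_run(tiny_dataset, configs, features=m[:, None], seed=2)
    assert run.results["planted"].metrics()["accuracy"] > 0.75


# --------------------------------------------------------------------------- #
# report assembly
# --------------------------------------------------------------------------- #
def test_assemble_report_structure(tiny_dataset, tmp_path):
    values = tiny_dataset.kinematics().sum(axis=1)[:, None]
    configs = {"kin": ScalarMetricConfig("kin")}
    run = loocv_run(tiny_dataset, configs, features=values, seed=6)
    boot = {"kin": bootstrap_run(tiny_dataset, ScalarMetricConfig("kin"), None,
                                 n_boot=5, seed=6, features=values)}
    report = assemble_report(run, bootstrap=boot)
    cols = set(report.loocv_table.columns)
    assert {"classifier", "accuracy", "sensitivity", "specificity",
            "auc_testing", "auc_training_mean", "auc_training_best",
            "auc_training_worst"} <= cols
    assert "err632plus" in report.bootstrap_table.columns
    report.save(tmp_path, plots=False)
    import pandas as pd

    back = pd.read_csv(tmp_path / "loocv_metrics.csv")
    pd.testing.assert_frame_equal(back, report.loocv_table)


def test_assemble_report_empty_error():
    from strainclass.evaluation import LoocvRun

    with pytest.raises(ValueError):
        assemble_report(LoocvRun(results={}, masks=None, selection=None))
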