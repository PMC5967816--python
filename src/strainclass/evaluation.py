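"""Cross-validation, bootstrap and null-label evaluation of the classifiers.

The evaluation protocol mirrors the study design:

* **Leave-one-out cross-validation** — each case is predicted by a model
  trained on the remaining n-1 cases; feature selection is redone inside
  every fold from the training cases only (avoiding selection bias). Held-out
  probabilities over all folds give a single testing ROC/AUC; each fold also
  yields a training AUC over its own n-1 cases, summarized as mean, 95% CI,
  best and worst.
* **Out-of-bootstrap** — repeated bootstrap resamples are used for training
  (with per-trial feature selection) and the unselected cases for testing;
  per-trial accuracy/sensitivity/specificity/AUC are summarized by mean and
  percentile 95% CI, together with the .632+ prediction error.
* **Randomized-label validation** — the full LOOCV is re-run on label
  permutations; the mean metrics are tested against the chance level 0.5 by
  two-tailed one-sample t-tests.

Scalar injury metrics enter the same protocols through univariate logistic
regression, so feature-based and scalar classifiers are compared on equal
footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._utils import derive_seed
from .classifiers import fit_classifier
from .data import Dataset
from .metrics import fit_univariate_logistic, predict_logistic
from .selection import SelectionConfig, select_features, selection_probability_map

__all__ = [
    "PredictionRecord",
    "ClassifierLoocv",
    "LoocvRun",
    "ScalarMetricConfig",
    "confusion_metrics",
    "roc_auc",
    "loocv_run",
    "bootstrap_run",
    "dot632plus_error",
    "randomized_label_test",
    "EvaluationReport",
    "assemble_report",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity")


# --------------------------------------------------------------------------- #
# elementary metrics
# --------------------------------------------------------------------------- #
def confusion_metrics(truth, predicted) -> dict:
    """Accuracy, sensitivity and specificity with concussion as positive."""
    y = np.asarray(truth, dtype=int).ravel()
    p = np.asarray(predicted, dtype=int).ravel()
    if y.size == 0:
        raise ValueError("no prediction records")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    out = {"accuracy": (tp + tn) / y.size}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else np.nan
    out["specificity"] = tn / (tn + fp) if (tn + fp) else np.nan
    out["confusion"] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
    return out


def roc_auc(p1, truth):
    """AUC (Mann-Whitney convention, ties counted 1/2) plus the ROC curve."""
    y = np.asarray(truth, dtype=int).ravel()
    s = np.asarray(p1, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes among the records")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, fpr, tpr


# --------------------------------------------------------------------------- #
# classifier configs usable in the protocols
# --------------------------------------------------------------------------- #
@dataclass
class ScalarMetricConfig:
    """A scalar injury metric classified via univariate logistic regression."""

    kind: str = field(default="logistic", init=False)
    metric_name: str = ""


class _ScalarLogistic:
    def __init__(self, model):
        self.model = model

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return predict_logistic(self.model, X[:, 0])


def _fit(config, X, y, mask, seed):
    """Fit any classifier config; returns an object with predict_proba."""
    if getattr(config, "kind", None) == "logistic":
        model = fit_univariate_logistic(
            np.asarray(X)[:, 0], y, metric_name=config.metric_name
        )
        return _ScalarLogistic(model)
    return fit_classifier(X, y, config, mask=mask, seed=seed)


def _uses_selection(config) -> bool:
    return getattr(config, "kind", None) in ("deep", "svm", "rf")


# --------------------------------------------------------------------------- #
# leave-one-out cross-validation
# --------------------------------------------------------------------------- #
@dataclass
class PredictionRecord:
    case_id: str
    fold_id: int
    p1: float
    predicted: int
    truth: int
    role: str = "test"


@dataclass
class ClassifierLoocv:
    """Held-out records and per-fold training AUCs for one classifier."""

    name: str
    records: list
    training_aucs: np.ndarray
    fold_train_probs: dict = field(default_factory=dict, repr=False)
    fold_train_truth: dict = field(default_factory=dict, repr=False)
    failed_folds: list = field(default_factory=list)

    @property
    def held_out_probs(self) -> np.ndarray:
        return np.array([r.p1 for r in self.records])

    @property
    def truth(self) -> np.ndarray:
        return np.array([r.truth for r in self.records])

    @property
    def predicted(self) -> np.ndarray:
        return np.array([r.predicted for r in self.records])

    def metrics(self) -> dict:
        return confusion_metrics(self.truth, self.predicted)

    def testing_auc(self) -> float:
        return roc_auc(self.held_out_probs, self.truth)[0]

    def training_auc_summary(self) -> dict:
        a = self.training_aucs[np.isfinite(self.training_aucs)]
        lo, hi = np.percentile(a, [2.5, 97.5])
        return {
            "mean": float(a.mean()),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "best": float(a.max()),
            "worst": float(a.min()),
        }

    def best_worst_fold_rocs(self) -> dict:
        """ROC curves of the best- and worst-AUC training folds."""
        out = {}
        for tag, fold in (
            ("best", int(np.nanargmax(self.training_aucs))),
            ("worst", int(np.nanargmin(self.training_aucs))),
        ):
            _, fpr, tpr = roc_auc(self.fold_train_probs[fold], self.fold_train_truth[fold])
            out[tag] = {"fold": fold, "fpr": fpr, "tpr": tpr,
                        "auc": float(self.training_aucs[fold])}
        return out


@dataclass
class LoocvRun:
    results: dict
    masks: list | None
    selection: SelectionConfig | None

    def probability_map(self, grid):
        if not self.masks:
            raise ValueError("no selection masks recorded for this run")
        return selection_probability_map(self.masks, grid)


def _loocv_matrix(X, y, configs: dict, selection: SelectionConfig | None,
                  seed: int, case_ids=None) -> LoocvRun:
    """LOOCV on a precomputed feature matrix; configs share fold selections."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    n = y.size
    if n < 4 or len(np.unique(y)) < 2:
        raise ValueError("LOOCV needs n >= 4 with both classes present")
    if case_ids is None:
        case_ids = [f"case{i:03d}" for i in range(n)]
    do_select = selection is not None and selection.method != "none"
    any_feature_clf = any(_uses_selection(c) for c in configs.values())

    per_clf = {
        name: ClassifierLoocv(name=name, records=[], training_aucs=np.zeros(n))
        for name in configs
    }
    masks = [] if (do_select and any_feature_clf) else None

    for k in range(n):
        train_idx = np.delete(np.arange(n), k)
        Xtr, ytr = X[train_idx], y[train_idx]
        fold_seed = derive_seed(seed, "fold", k)
        mask = None
        if masks is not None:
            mask = select_features(Xtr, ytr, selection,
                                   seed=derive_seed(fold_seed, "select"), fold_id=k)
            masks.append(mask)
        for name, config in configs.items():
            res = per_clf[name]
            try:
                clf = _fit(config, Xtr, ytr,
                           mask if _uses_selection(config) else None,
                           derive_seed(fold_seed, name))
            except Exception as exc:  # fold marked failed, surfaced in result
                res.failed_folds.append({"fold": k, "error": repr(exc)})
                res.training_aucs[k] = np.nan
                continue
            p_train = clf.predict_proba(Xtr)
            res.training_aucs[k] = roc_auc(p_train, ytr)[0]
            res.fold_train_probs[k] = p_train
            res.fold_train_truth[k] = ytr.copy()
            p1 = float(clf.predict_proba(X[k : k + 1])[0])
            res.records.append(
                PredictionRecord(
                    case_id=str(case_ids[k]), fold_id=k, p1=p1,
                    predicted=int(p1 >= 0.5), truth=int(y[k]),
                )
            )
    return LoocvRun(results=per_clf, masks=masks, selection=selection)


def loocv_run(dataset: Dataset, configs: dict,
              selection: SelectionConfig | None = None, seed: int = 0,
              features: np.ndarray | None = None) -> LoocvRun:
    """Leave-one-out evaluation of one or more classifier configs.

    ``configs`` maps a display name to a classifier config (DeepConfig,
    SVMConfig, RFConfig or ScalarMetricConfig). Feature-based configs share
    each fold's selection mask, since selection depends only on the fold's
    training cases and the seed.
    """
    if not configs:
        raise ValueError("no classifier configs given")
    if features is None:
        features = dataset.feature_matrix()
    return _loocv_matrix(features, dataset.labels, configs, selection, seed,
                         case_ids=dataset.case_ids)


# --------------------------------------------------------------------------- #
# bootstrap and .632+
# --------------------------------------------------------------------------- #
def dot632plus_error(err_train: float, err_oob: float, labels, train_predictions) -> float:
    """.632+ prediction error.

    gamma = p(1-q) + (1-p)q is the no-information error (p = observed
    positive rate, q = predicted positive rate of the full-data fit);
    err_oob is clamped to gamma, the relative overfitting rate
    R = (err_oob - err_train)/(gamma - err_train) is clipped to [0, 1], and
    the weight w = .632/(1 - .368 R) blends training and out-of-bag error.
    """
    for name, v in (("err_train", err_train), ("err_oob", err_oob)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a rate in [0, 1]")
    y = np.asarray(labels, dtype=int).ravel()
    q = float(np.mean(np.asarray(train_predictions, dtype=int).ravel() == 1))
    p = float(np.mean(y == 1))
    gamma = p * (1.0 - q) + (1.0 - p) * q
    err_oob = min(err_oob, gamma)  # overfitting clamp
    if err_oob > err_train and gamma > err_train:
        r = (err_oob - err_train) / (gamma - err_train)
    else:
        r = 0.0
    r = float(np.clip(r, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * r)
    return float((1.0 - w) * err_train + w * err_oob)


def bootstrap_run(dataset: Dataset, config, selection: SelectionConfig | None = None,
                  n_boot: int = 100, seed: int = 0,
                  features: np.ndarray | None = None,
                  max_redraws: int = 100) -> dict:
    """Out-of-bootstrap evaluation of one classifier + the .632+ error."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = dataset.feature_matrix() if features is None else np.asarray(features, float)
    y = dataset.labels
    n = y.size
    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    do_select = (selection is not None and selection.method != "none"
                 and _uses_selection(config))

    rows, redraw_log = [], 0
    for trial in range(n_boot):
        for _ in range(max_redraws):
            bag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), bag)
            _, bag_counts = np.unique(y[bag], return_counts=True)
            # every classifier needs >= 2 training cases per class
            if oob.size > 0 and bag_counts.size == 2 and bag_counts.min() >= 2:
                break
            redraw_log += 1
        else:
            raise RuntimeError("could not draw a usable bootstrap sample")
        trial_seed = derive_seed(seed, "trial", trial)
        mask = None
        if do_select:
            mask = select_features(X[bag], y[bag], selection,
                                   seed=derive_seed(trial_seed, "select"),
                                   fold_id=trial)
        clf = _fit(config, X[bag], y[bag], mask, derive_seed(trial_seed, "fit"))
        p_oob = clf.predict_proba(X[oob])
        pred = (np.asarray(p_oob) >= 0.5).astype(int)
        m = confusion_metrics(y[oob], pred)
        try:
            auc = roc_auc(p_oob, y[oob])[0]
        except ValueError:
            auc = np.nan
        rows.append({"trial": trial, "accuracy": m["accuracy"],
                     "sensitivity": m["sensitivity"],
                     "specificity": m["specificity"], "auc": auc,
                     "n_oob": int(oob.size)})
    trials = pd.DataFrame(rows)

    # .632+ from the full-data fit's resubstitution error and the OOB error
    full_mask = None
    if do_select:
        full_mask = select_features(X, y, selection,
                                    seed=derive_seed(seed, "select_full"), fold_id=-1)
    full_clf = _fit(config, X, y, full_mask, derive_seed(seed, "fit_full"))
    train_pred = (np.asarray(full_clf.predict_proba(X)) >= 0.5).astype(int)
    err_train = float(np.mean(train_pred != y))
    err_oob = float(1.0 - trials["accuracy"].mean())
    err632 = dot632plus_error(err_train, err_oob, y, train_pred)

    summary = {}
    for col in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = trials[col].to_numpy(dtype=float)
        ok = vals[np.isfinite(vals)]
        lo, hi = np.percentile(ok, [2.5, 97.5])
        summary[col] = {"mean": float(ok.mean()), "ci_low": float(lo),
                        "ci_high": float(hi)}
    return {"trials": trials, "summary": summary, "err632plus": err632,
            "err_train": err_train, "err_oob": err_oob, "redraws": redraw_log}


# --------------------------------------------------------------------------- #
# randomized-label validation
# --------------------------------------------------------------------------- #
def _ttest_vs_chance(values: np.ndarray, popmean: float = 0.5) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return np.nan
    if values.std(ddof=1) == 0:
        return 1.0 if values.mean() == popmean else 0.0
    return float(stats.ttest_1samp(values, popmean).pvalue)


def randomized_label_test(dataset: Dataset, configs: dict,
                          selection: SelectionConfig | None = None,
                          n_trials: int = 50, seed: int = 0,
                          features: np.ndarray | None = None) -> dict:
    """Re-run the full LOOCV on permuted labels, n_trials times.

    Permutations preserve the exact class counts. Returns per-trial metrics
    and, per classifier, the mean metrics with two-tailed one-sample t-test
    p-values against the chance level 0.5.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    X = dataset.feature_matrix() if features is None else np.asarray(features, float)
    y = dataset.labels
    rng = np.random.default_rng(derive_seed(seed, "permute"))
    rows = []
    for trial in range(n_trials):
        y_perm = rng.permutation(y)
        run = _loocv_matrix(X, y_perm, configs, selection,
                            seed=derive_seed(seed, "perm_trial", trial))
        for name, res in run.results.items():
            m = res.metrics()
            rows.append({"trial": trial, "classifier": name,
                         "accuracy": m["accuracy"],
                         "sensitivity": m["sensitivity"],
                         "specificity": m["specificity"],
                         "n_failed_folds": len(res.failed_folds)})
    trials = pd.DataFrame(rows)
    summary = {}
    for name in configs:
        sub = trials[trials["classifier"] == name]
        summary[name] = {}
        for metric in METRIC_NAMES:
            vals = sub[metric].to_numpy(dtype=float)
            summary[name][metric] = {
                "mean": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals, ddof=1)),
                "p_vs_0.5": _ttest_vs_chance(vals),
            }
    return {"trials": trials, "summary": summary, "n_trials": n_trials}


# --------------------------------------------------------------------------- #
# report assembly
# --------------------------------------------------------------------------- #
@dataclass
class EvaluationReport:
    """Tables and curves for one evaluation campaign."""

    loocv_table: pd.DataFrame
    testing_rocs: dict
    training_rocs: dict
    bootstrap_table: pd.DataFrame | None = None
    permutation_table: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def save(self, directory, plots: bool = True) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.loocv_table.to_csv(directory / "loocv_metrics.csv", index=False)
        if self.bootstrap_table is not None:
            self.bootstrap_table.to_csv(directory / "bootstrap_metrics.csv", index=False)
        if self.permutation_table is not None:
            self.permutation_table.to_csv(directory / "randomized_label_metrics.csv",
                                          index=False)
        roc_rows = []
        for name, (fpr, tpr) in self.testing_rocs.items():
            for f, t in zip(fpr, tpr):
                roc_rows.append({"classifier": name, "dataset": "testing",
                                 "fpr": f, "tpr": t})
        for name, curves in self.training_rocs.items():
            for tag, c in curves.items():
                for f, t in zip(c["fpr"], c["tpr"]):
                    roc_rows.append({"classifier": name, "dataset": f"training_{tag}",
                                     "fpr": f, "tpr": t})
        pd.DataFrame(roc_rows).to_csv(directory / "roc_curves.csv", index=False)
        if self.notes:
            (directory / "notes.txt").write_text("\n".join(self.notes) + "\n")
        if plots:
            self._plot(directory)

    def _plot(self, directory) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for name, (fpr, tpr) in self.testing_rocs.items():
            ax.plot(fpr, tpr, label=name)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title("Testing ROC (held-out LOOCV probabilities)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(directory / "roc_testing.svg")
        plt.close(fig)


def assemble_report(loocv: LoocvRun, bootstrap: dict | None = None,
                    permutation: dict | None = None) -> EvaluationReport:
    """Collect LOOCV/bootstrap/permutation outputs into one report."""
    if not loocv.results:
        raise ValueError("no classifier results to report")
    rows, testing_rocs, training_rocs, notes = [], {}, {}, []
    for name, res in loocv.results.items():
        if not res.records:
            notes.append(f"{name}: no successful folds, omitted")
            continue
        m = res.metrics()
        tr = res.training_auc_summary()
        try:
            auc_t, fpr, tpr = roc_auc(res.held_out_probs, res.truth)
            testing_rocs[name] = (fpr, tpr)
            training_rocs[name] = res.best_worst_fold_rocs()
        except ValueError:
            notes.append(f"{name}: testing ROC unavailable "
                         "(single class among successful folds)")
            auc_t = np.nan
        rows.append({"classifier": name, "accuracy": m["accuracy"],
                     "sensitivity": m["sensitivity"],
                     "specificity": m["specificity"], "auc_testing": auc_t,
                     "auc_training_mean": tr["mean"],
                     "auc_training_ci_low": tr["ci_low"],
                     "auc_training_ci_high": tr["ci_high"],
                     "auc_training_best": tr["best"],
                     "auc_training_worst": tr["worst"]})
        if res.failed_folds:
            notes.append(f"{name}: {len(res.failed_folds)} failed folds")
    boot_table = None
    if bootstrap:
        brows = []
        for name, b in bootstrap.items():
            row = {"classifier": name, "err632plus": b["err632plus"]}
            for metric, s in b["summary"].items():
                row[f"{metric}_mean"] = s["mean"]
                row[f"{metric}_ci_low"] = s["ci_low"]
                row[f"{metric}_ci_high"] = s["ci_high"]
            brows.append(row)
        boot_table = pd.DataFrame(brows)
    perm_table = None
    if permutation:
        prows = []
        for name, metrics in permutation["summary"].items():
            row = {"classifier": name}
            for metric, s in metrics.items():
                row[f"{metric}_mean"] = s["mean"]
                row[f"{metric}_p_vs_0.5"] = s["p_vs_0.5"]
            prows.append(row)
        perm_table = pd.DataFrame(prows)
    return EvaluationReport(
        loocv_table=pd.DataFrame(rows),
        testing_rocs=testing_rocs,
        training_rocs=training_rocs,
        bootstrap_table=boot_table,
        permutation_table=perm_table,
        notes=notes,
    )
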