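"""The three feature-based classifiers behind one contract.

Each classifier is fit on a training matrix of (optionally pre-selected)
voxel features and emits a per-case concussion probability p1, with the
decision rule p1 >= 0.5. A fitted classifier stores the selection mask it
was trained with and applies it internally, so callers always pass
full-length feature vectors.

* deep — the five-layer pyramid network (see :mod:`strainclass.network`);
* svm  — linear-kernel maximum-margin fit, with probabilities from a
  monotone logistic calibration of the decision values on the training data;
* rf   — an ensemble of independently seeded random forests ("trials");
  the reported probability is the mean per-trial vote fraction and the full
  per-trial distribution is kept for confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from ._utils import derive_seed
from .metrics import fit_univariate_logistic, predict_logistic
from .network import NetworkSpec, TrainingConfig, TrainedDeepNet, desk_spec, train_deep
from .selection import SelectionMask

__all__ = [
    "DeepConfig",
    "SVMConfig",
    "RFConfig",
    "TrainedClassifier",
    "fit_classifier",
    "train_svm",
    "train_rf",
]


@dataclass
class DeepConfig:
    """Deep classifier: widths template + training hyperparameters."""

    kind: str = field(default="deep", init=False)
    layer_widths: tuple | None = None  # None -> desk pyramid scaled to input
    first_width: int = 48
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def build_spec(self, input_dim: int) -> NetworkSpec:
        if self.layer_widths is not None:
            return NetworkSpec(input_dim, tuple(self.layer_widths))
        return desk_spec(input_dim, self.first_width)


@dataclass
class SVMConfig:
    kind: str = field(default="svm", init=False)
    C: float = 1.0  # soft-margin cost; not stated for the original study


@dataclass
class RFConfig:
    """Random-forest classifier: tree count/depth and repeated trials.

    Paper-scale defaults are 45 trees of depth 64 without feature selection
    (75/8 or 75/12 with selection) and 100 trials per prediction.
    """

    kind: str = field(default="rf", init=False)
    n_trees: int = 45
    max_depth: int | None = 64
    n_trials: int = 100


@dataclass
class TrainedClassifier:
    """Fitted classifier + the selection mask it was trained with."""

    kind: str
    model: object
    mask: SelectionMask | None = None
    diagnostics: dict = field(default_factory=dict)
    trial_probs_train: np.ndarray | None = None  # rf only: trials x cases

    def _select(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mask is not None:
            return self.mask.apply(X)
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Concussion probability p1 per case (full-length feature input)."""
        Xs = self._select(X)
        if self.kind == "deep":
            return self.model.predict_proba(Xs)
        if self.kind == "svm":
            calib, svc = self.model
            return predict_logistic(calib, svc.decision_function(Xs))
        if self.kind == "rf":
            return self.predict_trials(X).mean(axis=0)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def predict_trials(self, X) -> np.ndarray:
        """RF only: per-trial probability matrix (n_trials x n_cases)."""
        if self.kind != "rf":
            raise ValueError("per-trial predictions exist only for rf")
        Xs = self._select(X)
        return np.stack([f.predict_proba(Xs)[:, _pos_col(f)] for f in self.model])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _pos_col(forest) -> int:
    return int(np.flatnonzero(forest.classes_ == 1)[0])


def _check_input(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be a cases x voxels matrix matching labels")
    classes = np.unique(y)
    if set(classes.tolist()) != {0, 1}:
        raise ValueError("both classes must be present")
    return X, y


def train_svm(features, labels, config: SVMConfig) -> TrainedClassifier:
    """Linear-kernel SVM with logistic calibration of the decision value."""
    X, y = _check_input(features, labels)
    svc = SVC(kernel="linear", C=config.C)
    svc.fit(X, y)
    decision = svc.decision_function(X)
    calib = fit_univariate_logistic(decision, y, metric_name="svm_decision")
    return TrainedClassifier(
        kind="svm",
        model=(calib, svc),
        diagnostics={"n_support": svc.n_support_.tolist(),
                     "calibration_separated": calib.separated},
    )


def train_rf(features, labels, config: RFConfig, seed: int = 0) -> TrainedClassifier:
    """Ensemble of independently seeded forests (one per trial)."""
    X, y = _check_input(features, labels)
    if config.n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    forests = []
    for trial in range(config.n_trials):
        rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=derive_seed(seed, "rf_trial", trial),
            n_jobs=1,
        )
        rf.fit(X, y)
        forests.append(rf)
    clf = TrainedClassifier(kind="rf", model=forests,
                            diagnostics={"n_trials": config.n_trials})
    clf.trial_probs_train = clf.predict_trials(X)
    return clf


def fit_classifier(
    features,
    labels,
    config,
    mask: SelectionMask | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit any of the three classifiers on (masked) training features."""
    X, y = _check_input(features, labels)
    Xs = mask.apply(X) if mask is not None else X
    if config.kind == "deep":
        spec = config.build_spec(Xs.shape[1])
        tcfg = replace(config.training, seed=derive_seed(seed, "deep"))
        net: TrainedDeepNet = train_deep(Xs, y, spec, tcfg)
        clf = TrainedClassifier(kind="deep", model=net, diagnostics=net.diagnostics)
    elif config.kind == "svm":
        clf = train_svm(Xs, y, config)
    elif config.kind == "rf":
        clf = train_rf(Xs, y, config, seed=derive_seed(seed, "rf"))
    else:
        raise ValueError(f"unknown classifier kind {config.kind!r}")
    clf.mask = mask
    return clf
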