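"""Voxel-wise feature selection: F-score ranking and random-forest voting.

Two schemes mirror standard practice for high-dimensional, small-n imaging
features:

* **F-score** — for each voxel, the between-class squared deviations of the
  class means from the overall mean divided by the summed within-class
  variances; the top fraction (default 4%) is retained.
* **RF voting** — many independently seeded random forests are fit; after
  each run the top 1% of voxels by mean impurity-decrease (gini) importance
  receive one vote; the top 1% most-voted voxels are the final selection.

Selections are computed per cross-validation fold from the training cases
only; aggregating the per-fold masks yields a per-voxel selection-frequency
("probability") map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._utils import derive_seed, round_half_up
from .grid import VolumeGrid

__all__ = [
    "SelectionMask",
    "SelectionProbabilityMap",
    "SelectionConfig",
    "fscore_rank",
    "select_top_fraction",
    "rf_vote_select",
    "select_features",
    "selection_probability_map",
]


@dataclass
class SelectionMask:
    """Chosen WM-voxel feature indices for one fold."""

    indices: np.ndarray
    method: str  # "fscore" | "rfvote"
    fold_id: int = -1

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        if self.method not in ("fscore", "rfvote"):
            raise ValueError(f"unknown selection method {self.method!r}")

    def __len__(self) -> int:
        return int(self.indices.size)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.indices]


@dataclass
class SelectionConfig:
    """How to select features inside each fold."""

    method: str = "rfvote"  # "fscore" | "rfvote" | "none"
    fraction: float = 0.04  # F-score retention fraction
    n_runs: int = 200  # RF-voting runs (paper-scale: 5000)
    per_run_fraction: float = 0.01
    final_fraction: float = 0.01
    rf_n_trees: int = 45
    rf_max_depth: int | None = 64


def _check_two_classes(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if set(classes.tolist()) != {0, 1} or counts.min() < 2:
        raise ValueError("feature selection needs >= 2 cases in each class")


def fscore_rank(features: np.ndarray, labels) -> np.ndarray:
    """Per-voxel F-score.

    F_j = ((m1_j - m_j)^2 + (m0_j - m_j)^2) / (s1_j^2 + s0_j^2)

    with class means m1/m0, overall mean m and within-class sample variances
    s1^2/s0^2. Voxels constant overall score 0; voxels constant within both
    classes but differing between them get the maximum-score convention
    (largest finite score, so they sort first).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    _check_two_classes(y)
    X1, X0 = X[y == 1], X[y == 0]
    m, m1, m0 = X.mean(axis=0), X1.mean(axis=0), X0.mean(axis=0)
    num = (m1 - m) ** 2 + (m0 - m) ** 2
    den = X1.var(axis=0, ddof=1) + X0.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[np.ptp(X, axis=0) == 0] = 0.0  # constant overall
    inf_mask = ~np.isfinite(scores)
    if inf_mask.any():
        finite = scores[~inf_mask]
        top = finite.max() if finite.size else 1.0
        scores[inf_mask] = max(top, 1.0) * 2.0
    return scores


def select_top_fraction(scores: np.ndarray, fraction: float,
                        method: str = "fscore", fold_id: int = -1) -> SelectionMask:
    """Retain the round(fraction*N) highest-scoring voxels.

    Ties at the cutoff are broken toward the lowest voxel index (stable sort
    on descending score).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    k = round_half_up(fraction * scores.size)
    order = np.argsort(-scores, kind="stable")
    return SelectionMask(indices=np.sort(order[:k]), method=method, fold_id=fold_id)


def rf_vote_select(
    features,
    labels,
    n_runs: int = 200,
    per_run_fraction: float = 0.01,
    final_fraction: float = 0.01,
    seed: int = 0,
    n_trees: int = 45,
    max_depth: int | None = 64,
    fold_id: int = -1,
) -> SelectionMask:
    """Random-forest voting selection.

    Each of ``n_runs`` freshly seeded forests ranks voxels by impurity
    decrease; the top ``per_run_fraction`` of voxels per run each get one
    (unweighted) vote, and the final mask keeps the ``final_fraction`` most
    voted voxels (vote ties broken toward the lowest voxel index).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    _check_two_classes(y)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n_vox = X.shape[1]
    k_run = round_half_up(per_run_fraction * n_vox)
    votes = np.zeros(n_vox, dtype=np.int64)
    for run in range(n_runs):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            random_state=derive_seed(seed, "rfvote", run),
            n_jobs=1,
        )
        rf.fit(X, y)
        order = np.argsort(-rf.feature_importances_, kind="stable")
        votes[order[:k_run]] += 1
    return select_top_fraction(
        votes.astype(float), final_fraction, method="rfvote", fold_id=fold_id
    )


def select_features(
    features, labels, config: SelectionConfig, seed: int = 0, fold_id: int = -1
) -> SelectionMask | None:
    """Dispatch one fold's selection; ``method='none'`` returns None."""
    if config.method == "none":
        return None
    if config.method == "fscore":
        return select_top_fraction(
            fscore_rank(features, labels), config.fraction,
            method="fscore", fold_id=fold_id,
        )
    if config.method == "rfvote":
        return rf_vote_select(
            features,
            labels,
            n_runs=config.n_runs,
            per_run_fraction=config.per_run_fraction,
            final_fraction=config.final_fraction,
            seed=seed,
            n_trees=config.rf_n_trees,
            max_depth=config.rf_max_depth,
            fold_id=fold_id,
        )
    raise ValueError(f"unknown selection method {config.method!r}")


# --------------------------------------------------------------------------- #
# cross-fold probability maps
# --------------------------------------------------------------------------- #
@dataclass
class SelectionProbabilityMap:
    """Per-voxel frequency of selection across cross-validation folds."""

    frequency: np.ndarray
    n_folds: int
    method: str

    def threshold_mask(self, min_frequency: float = 0.5) -> np.ndarray:
        """Boolean feature mask of voxels selected with frequency > cutoff."""
        return self.frequency > min_frequency

    def to_volume(self, grid: VolumeGrid) -> np.ndarray:
        return grid.unflatten(self.frequency)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"voxel_index": np.arange(self.frequency.size), "frequency": self.frequency}
        )


def selection_probability_map(masks, grid: VolumeGrid) -> SelectionProbabilityMap:
    """Aggregate per-fold masks into a selection-frequency map."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one selection mask")
    methods = {m.method for m in masks}
    if len(methods) != 1:
        raise ValueError(f"mixed selection methods {sorted(methods)}")
    counts = np.zeros(grid.n_wm, dtype=np.int64)
    for m in masks:
        if m.indices.size and m.indices.max() >= grid.n_wm:
            raise ValueError("selection mask index exceeds N_WM")
        counts[m.indices] += 1
    return SelectionProbabilityMap(
        frequency=counts / len(masks), n_folds=len(masks), method=methods.pop()
    )
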