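"""Fully connected classification network, trained with ADAM in NumPy.

The network is a five-layer pyramid of fully connected layers that
progressively compresses the voxel-wise fiber-strain feature vector into a
two-unit output, turned into class probabilities (p1, p2) by a Softmax;
concussion is called when p1 >= 0.5. Layer l applies

    x_l = W_l a_{l-1} + b_l,   a_l = sigma_l(x_l)

with the activation schedule ReLU+batch-norm, ReLU, ReLU, Sigmoid, identity
(batch normalization on the first layer only: batch statistics during
training, stored running statistics at inference; within the first layer the
affine output is batch-normalized and then rectified).

Training minimizes the softmax cross-entropy by ADAM on batches of 5 (a
short final batch is topped up by randomly resampled training cases). A
stratified 10% split of the training cases serves as internal validation:
if the validation error has not decreased from its initial value after a
probe period, the attempt is abandoned as badly initialized and restarted
(bounded); training stops at the first epoch past the admissible minimum at
which the validation error has not improved for `patience` epochs, and the
best-validation parameters are kept.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from ._utils import derive_seed

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedDeepNet",
    "TrainingError",
    "paper_full_spec",
    "paper_reduced_spec",
    "desk_spec",
    "parameter_count",
    "forward",
    "train_deep",
]

_ACTIVATIONS = ("relu_bn", "relu", "sigmoid", "identity")
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9

# paper-scale activation schedule for the five-layer pyramid
PYRAMID_ACTIVATIONS = ("relu_bn", "relu", "relu", "sigmoid", "identity")


class TrainingError(RuntimeError):
    """Raised when network training fails (NaN loss, exhausted restarts)."""


@dataclass
class NetworkSpec:
    """Layer widths, activation schedule and (once initialized) parameters."""

    input_dim: int
    layer_widths: tuple
    activations: tuple = PYRAMID_ACTIVATIONS
    weights: list = field(default_factory=list, repr=False)
    biases: list = field(default_factory=list, repr=False)
    bn_params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.layer_widths = tuple(int(w) for w in self.layer_widths)
        self.activations = tuple(self.activations)
        if self.layer_widths[-1] != 2:
            raise ValueError("final layer must have 2 units (p1, p2)")
        if len(self.activations) != len(self.layer_widths):
            raise ValueError("one activation per layer required")
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths)

    def dims(self):
        """(out, in) shape of each weight matrix."""
        ins = (self.input_dim,) + self.layer_widths[:-1]
        return [(o, i) for o, i in zip(self.layer_widths, ins)]

    def initialize(self, rng: np.random.Generator) -> None:
        """He initialization for ReLU layers, Glorot for sigmoid/identity."""
        self.weights, self.biases, self.bn_params = [], [], {}
        for l, ((out, inp), act) in enumerate(zip(self.dims(), self.activations)):
            if act.startswith("relu"):
                scale = math.sqrt(2.0 / inp)
            else:
                scale = math.sqrt(2.0 / (inp + out))
            self.weights.append(rng.normal(0.0, scale, size=(out, inp)))
            self.biases.append(np.zeros(out))
            if act == "relu_bn":
                self.bn_params[l] = {
                    "gamma": np.ones(out),
                    "beta": np.zeros(out),
                    "running_mean": np.zeros(out),
                    "running_var": np.ones(out),
                }

    @property
    def initialized(self) -> bool:
        return len(self.weights) == self.n_layers


def parameter_count(input_dim: int, layer_widths, include_bias: bool = True) -> int:
    """Number of independent parameters of the pyramid network.

    With ``include_bias=False`` only the weight-matrix entries are counted.
    """
    widths = [int(input_dim)] + [int(w) for w in layer_widths]
    total = sum(o * i for i, o in zip(widths[:-1], widths[1:]))
    if include_bias:
        total += sum(widths[1:])
    return total


def paper_full_spec() -> NetworkSpec:
    """Full-scale network: 64272 input, widths 2000-1000-500-250-2."""
    return NetworkSpec(64272, (2000, 1000, 500, 250, 2))


def paper_reduced_spec(input_dim: int = 643) -> NetworkSpec:
    """Reduced network for selected features: widths 500-250-125-60-2."""
    return NetworkSpec(input_dim, (500, 250, 125, 60, 2))


def desk_spec(input_dim: int, first_width: int = 48) -> NetworkSpec:
    """Desk-scale pyramid: five layers, each ~half the previous width."""
    widths = []
    w = first_width
    for _ in range(4):
        widths.append(max(w, 3))
        w //= 2
    widths.append(2)
    return NetworkSpec(input_dim, tuple(widths))


@dataclass
class TrainingConfig:
    """ADAM and early-stopping hyperparameters.

    Paper-scale defaults; the desk preset (``presets.desk_training_config``)
    retunes the learning rate and epoch range for small inputs.
    """

    learning_rate: float = 2e-8
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    momentum: float = 0.5  # compatibility flag only: ADAM's beta values fully
    # specify the update, so this field is documented as a no-op
    batch_size: int = 5
    max_epochs: int = 5000
    min_epochs: int = 1000
    probe_epochs: int = 300
    validation_fraction: float = 0.10
    patience: int = 200
    max_restarts: int = 5
    strict_restarts: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if not (self.probe_epochs < self.min_epochs <= self.max_epochs):
            raise ValueError("need probe_epochs < min_epochs <= max_epochs")


# --------------------------------------------------------------------------- #
# forward / backward
# --------------------------------------------------------------------------- #
def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_batch(spec: NetworkSpec, X: np.ndarray, train: bool, cache=None):
    """Forward pass; in train mode records intermediates for backprop."""
    A = np.asarray(X, dtype=np.float64)
    if A.ndim == 1:
        A = A[None, :]
    if A.shape[1] != spec.input_dim:
        raise ValueError(
            f"input dim {A.shape[1]} does not match network input {spec.input_dim}"
        )
    if not spec.initialized:
        raise ValueError("network parameters are not initialized")
    for l in range(spec.n_layers):
        Z = A @ spec.weights[l].T + spec.biases[l]
        act = spec.activations[l]
        if act == "relu_bn":
            bn = spec.bn_params[l]
            if train:
                mu = Z.mean(axis=0)
                var = Z.var(axis=0)
                bn["running_mean"] = (
                    _BN_MOMENTUM * bn["running_mean"] + (1 - _BN_MOMENTUM) * mu
                )
                bn["running_var"] = (
                    _BN_MOMENTUM * bn["running_var"] + (1 - _BN_MOMENTUM) * var
                )
            else:
                mu, var = bn["running_mean"], bn["running_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            Zhat = (Z - mu) * inv_std
            H = bn["gamma"] * Zhat + bn["beta"]
            out = np.maximum(H, 0.0)
            if cache is not None:
                cache.append(
                    {"A_in": A, "Z": Z, "Zhat": Zhat, "inv_std": inv_std, "H": H}
                )
        elif act == "relu":
            out = np.maximum(Z, 0.0)
            if cache is not None:
                cache.append({"A_in": A, "Z": Z})
        elif act == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-np.clip(Z, -60, 60)))
            if cache is not None:
                cache.append({"A_in": A, "out": out})
        else:  # identity
            out = Z
            if cache is not None:
                cache.append({"A_in": A})
        A = out
    return _softmax(A)


def forward(spec: NetworkSpec, x0: np.ndarray):
    """Probabilities (p1, p2) for one feature vector (inference mode)."""
    p = _forward_batch(spec, np.atleast_2d(x0), train=False)
    return float(p[0, 0]), float(p[0, 1])


def predict_proba(spec: NetworkSpec, X: np.ndarray) -> np.ndarray:
    """Concussion probability p1 per row of X (inference mode)."""
    return _forward_batch(spec, X, train=False)[:, 0]


def _backward_batch(spec, cache, probs, targets):
    """Gradients of mean softmax cross-entropy w.r.t. all parameters."""
    B = probs.shape[0]
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), targets] = 1.0
    dZ = (probs - onehot) / B  # grad at the last affine output (identity+softmax)
    grads_W, grads_b, grads_bn = [None] * spec.n_layers, [None] * spec.n_layers, {}
    dA = dZ
    for l in range(spec.n_layers - 1, -1, -1):
        act = spec.activations[l]
        c = cache[l]
        if act == "identity":
            dZl = dA
        elif act == "sigmoid":
            dZl = dA * c["out"] * (1.0 - c["out"])
        elif act == "relu":
            dZl = dA * (c["Z"] > 0)
        else:  # relu_bn: back through ReLU, then batch norm
            bn = spec.bn_params[l]
            dH = dA * (c["H"] > 0)
            dgamma = (dH * c["Zhat"]).sum(axis=0)
            dbeta = dH.sum(axis=0)
            dZhat = dH * bn["gamma"]
            m = dH.shape[0]
            dZl = (
                c["inv_std"]
                / m
                * (
                    m * dZhat
                    - dZhat.sum(axis=0)
                    - c["Zhat"] * (dZhat * c["Zhat"]).sum(axis=0)
                )
            )
            grads_bn[l] = {"gamma": dgamma, "beta": dbeta}
        grads_W[l] = dZl.T @ c["A_in"]
        grads_b[l] = dZl.sum(axis=0)
        if l > 0:
            dA = dZl @ spec.weights[l]
    return grads_W, grads_b, grads_bn


class _Adam:
    def __init__(self, config: TrainingConfig):
        self.lr = config.learning_rate
        self.b1, self.b2, self.eps = (
            config.adam_beta1,
            config.adam_beta2,
            config.adam_eps,
        )
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _cross_entropy(spec, X, y) -> float:
    probs = _forward_batch(spec, X, train=False)
    targets = 1 - np.asarray(y, dtype=int)  # unit 0 is the concussion unit
    p = np.clip(probs[np.arange(len(y)), targets], 1e-12, 1.0)
    return float(-np.log(p).mean())


def _stratified_split(y, fraction, rng):
    """Validation indices: `fraction` of each class, at least one case."""
    y = np.asarray(y, dtype=int)
    val = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = max(1, int(round(fraction * idx.size)))
        val.extend(idx[:k].tolist())
    val = np.array(sorted(val))
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


@dataclass
class TrainedDeepNet:
    """A trained network plus its training diagnostics."""

    spec: NetworkSpec
    config: TrainingConfig
    diagnostics: dict

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self.spec, X)


def _params_view(spec: NetworkSpec) -> dict:
    params = {}
    for l in range(spec.n_layers):
        params[("W", l)] = spec.weights[l]
        params[("b", l)] = spec.biases[l]
        if l in spec.bn_params:
            params[("gamma", l)] = spec.bn_params[l]["gamma"]
            params[("beta", l)] = spec.bn_params[l]["beta"]
    return params


def _snapshot(spec: NetworkSpec):
    return (
        [w.copy() for w in spec.weights],
        [b.copy() for b in spec.biases],
        copy.deepcopy(spec.bn_params),
    )


def _restore(spec: NetworkSpec, snap) -> None:
    spec.weights = [w.copy() for w in snap[0]]
    spec.biases = [b.copy() for b in snap[1]]
    spec.bn_params = copy.deepcopy(snap[2])


def train_deep(
    features: np.ndarray,
    labels: np.ndarray,
    spec_template: NetworkSpec,
    config: TrainingConfig,
) -> TrainedDeepNet:
    """Train the network with ADAM, internal validation and early stopping."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if set(classes.tolist()) != {0, 1} or counts.min() < 2:
        raise TrainingError("need >= 2 cases per class to train")
    if X.shape[1] != spec_template.input_dim:
        raise TrainingError(
            f"feature dim {X.shape[1]} != network input {spec_template.input_dim}"
        )

    rng = np.random.default_rng(derive_seed(config.seed, "train_deep"))
    train_idx, val_idx = _stratified_split(y, config.validation_fraction, rng)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    targets_tr = 1 - ytr  # output unit 0 carries the concussion probability

    best_overall = None  # (val_err, snapshot, diag) across attempts
    warnings_log = []

    for attempt in range(config.max_restarts + 1):
        spec = NetworkSpec(
            spec_template.input_dim,
            spec_template.layer_widths,
            spec_template.activations,
        )
        spec.initialize(rng)
        adam = _Adam(config)
        initial_val = _cross_entropy(spec, Xval, yval)
        best_val, best_epoch, best_snap = np.inf, -1, _snapshot(spec)
        train_curve, val_curve = [], []
        probe_failed = False
        epoch = 0
        n_tr = len(train_idx)

        for epoch in range(1, config.max_epochs + 1):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n_tr, config.batch_size):
                batch = order[start : start + config.batch_size]
                if batch.size < config.batch_size:
                    extra = rng.integers(0, n_tr, size=config.batch_size - batch.size)
                    batch = np.concatenate([batch, extra])
                cache = []
                probs = _forward_batch(spec, Xtr[batch], train=True, cache=cache)
                tgt = targets_tr[batch]
                loss = -np.log(
                    np.clip(probs[np.arange(len(tgt)), tgt], 1e-12, 1.0)
                ).mean()
                if not np.isfinite(loss):
                    raise TrainingError(f"NaN/inf loss at epoch {epoch}")
                gW, gb, gbn = _backward_batch(spec, cache, probs, tgt)
                grads = {}
                for l in range(spec.n_layers):
                    grads[("W", l)] = gW[l]
                    grads[("b", l)] = gb[l]
                for l, g in gbn.items():
                    grads[("gamma", l)] = g["gamma"]
                    grads[("beta", l)] = g["beta"]
                adam.step(_params_view(spec), grads)
                epoch_loss += loss
                n_batches += 1
            val_err = _cross_entropy(spec, Xval, yval)
            train_curve.append(epoch_loss / n_batches)
            val_curve.append(val_err)
            if val_err < best_val:
                best_val, best_epoch, best_snap = val_err, epoch, _snapshot(spec)
            if epoch == config.probe_epochs and best_val >= initial_val:
                probe_failed = True
                break
            if epoch >= config.min_epochs and epoch - best_epoch >= config.patience:
                break

        diag = {
            "epochs_run": epoch,
            "attempt": attempt,
            "initial_val_error": initial_val,
            "best_val_error": float(best_val),
            "best_epoch": best_epoch,
            "train_curve": train_curve,
            "val_curve": val_curve,
            "val_indices": val_idx.tolist(),
        }
        if best_overall is None or best_val < best_overall[0]:
            best_overall = (best_val, best_snap, spec, diag)
        if not probe_failed:
            _restore(spec, best_snap)
            diag["restarts"] = attempt
            diag["warnings"] = warnings_log
            return TrainedDeepNet(spec=spec, config=config, diagnostics=diag)
        warnings_log.append(
            f"attempt {attempt}: validation error did not decrease within "
            f"{config.probe_epochs} probe epochs; restarting"
        )

    # every attempt failed the probe
    if config.strict_restarts:
        raise TrainingError(
            f"all {config.max_restarts + 1} initializations failed the "
            f"{config.probe_epochs}-epoch validation probe: {warnings_log}"
        )
    _, best_snap, spec, diag = best_overall
    _restore(spec, best_snap)
    diag["restarts"] = config.max_restarts
    warnings_log.append("all probes failed; keeping the best attempt's parameters")
    diag["warnings"] = warnings_log
    return TrainedDeepNet(spec=spec, config=config, diagnostics=diag)
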