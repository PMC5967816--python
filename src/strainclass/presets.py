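"""Scale presets tying the stages into reproducible study conditions.

Two presets exist:

* ``desk`` — a 32^3 grid (~4k WM voxels), a 48-24-12-6-2 pyramid network
  trained for 30-100 epochs at learning rate 1e-3, 25-tree depth-8 forests
  with 5 trials, and 200 RF-voting runs. This is the default problem size
  for tests and examples; it keeps a full evaluation campaign within minutes
  on one CPU while preserving every structural property of the protocol.
* ``paper`` — the full-scale configuration: ~64k WM voxels, the
  2000-1000-500-250-2 network (reduced 500-250-125-60-2 after selection)
  with learning rate 2e-8 (1e-6 reduced), epochs in [1000, 5000] with a
  300-epoch probe, 45/64 or 75/8 / 75/12 tree forests with 100 trials, and
  5000 voting runs.
"""

from __future__ import annotations

from dataclasses import replace

from .classifiers import DeepConfig, RFConfig, SVMConfig
from .network import TrainingConfig
from .selection import SelectionConfig
from .synthetic import GeneratorConfig

__all__ = [
    "desk_generator_config",
    "desk_training_config",
    "paper_training_config",
    "classifier_suite",
    "selection_config",
    "SCALES",
]

SCALES = ("desk", "paper")


def desk_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **overrides)


def paper_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """~64k WM voxels (82^3 grid), matching the full study's feature count."""
    overrides.setdefault("grid_shape", (82, 82, 82))
    return GeneratorConfig(seed=seed, **overrides)


def desk_training_config(seed: int = 0) -> TrainingConfig:
    """Deep-training hyperparameters retuned for desk-scale inputs."""
    return TrainingConfig(
        learning_rate=1e-3,
        max_epochs=100,
        min_epochs=30,
        probe_epochs=10,
        patience=15,
        seed=seed,
    )


def paper_training_config(seed: int = 0, reduced: bool = False) -> TrainingConfig:
    return TrainingConfig(learning_rate=1e-6 if reduced else 2e-8, seed=seed)


def selection_config(method: str = "rfvote", scale: str = "desk") -> SelectionConfig:
    """Per-fold selection settings for one scale."""
    if scale == "paper":
        return SelectionConfig(method=method, n_runs=5000,
                               rf_n_trees=75, rf_max_depth=8)
    return SelectionConfig(method=method, n_runs=200, rf_n_trees=25, rf_max_depth=8)


def classifier_suite(scale: str = "desk", selected: bool = True, seed: int = 0) -> dict:
    """The three feature-based classifier configs for one scale.

    ``selected`` says whether features will be pre-selected per fold, which
    at paper scale switches the network to its reduced variant and the RF to
    its shallower tuning.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "paper":
        if selected:
            return {
                "deep": DeepConfig(layer_widths=(500, 250, 125, 60, 2),
                                   training=paper_training_config(seed, reduced=True)),
                "svm": SVMConfig(),
                "rf": RFConfig(n_trees=75, max_depth=12, n_trials=100),
            }
        return {
            "deep": DeepConfig(layer_widths=(2000, 1000, 500, 250, 2),
                               training=paper_training_config(seed)),
            "svm": SVMConfig(),
            "rf": RFConfig(n_trees=45, max_depth=64, n_trials=100),
        }
    return {
        "deep": DeepConfig(first_width=48, training=desk_training_config(seed)),
        "svm": SVMConfig(),
        "rf": RFConfig(n_trees=25, max_depth=8, n_trials=5),
    }
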