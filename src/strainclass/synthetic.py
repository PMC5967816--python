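"""Synthetic strain-impact datasets with known ground truth.

The generator emulates the statistical structure the classification study
assumes, at a configurable grid size:

* a procedurally built brain/WM geometry with seven connected ROI blobs
  (corpus callosum, left/right superior longitudinal fasciculus, left/right
  external capsule, brainstem, and a catch-all "other-WM" label);
* per-case non-negative peak-strain fields: a latent log-normal impact
  severity scales a fixed smooth baseline pattern times a positive,
  spatially correlated random field; fiber strain is a voxel-wise attenuated
  copy of MPS (attenuation in (0,1], so fiber <= MPS everywhere);
* injury labels driven by the mean fiber strain over a small set of planted
  discriminative ROIs, with the class separation calibrated to a requested
  effect size (in within-class SD units) and exact 25/33 class counts;
* peak angular-velocity kinematics correlated with the latent severity.

Ground truth (planted voxel indices, per-case severities) is carried in the
dataset provenance so recovery tests can score selection and classification
against it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from ._utils import derive_seed
from .data import Dataset, StrainCase, write_dataset
from .grid import ROI_LABELS, VolumeGrid

__all__ = ["GeneratorConfig", "make_grid", "generate_dataset", "ground_truth",
           "write_synthetic_dataset", "GenerationError"]


class GenerationError(RuntimeError):
    """Raised when the generator cannot satisfy its own constraints."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the study design: 58 impacts, 25 concussions, class
    signal planted in SLF-R and EC-L (the tracts that dominate the selection
    maps), and an effect size large enough that feature-based classifiers
    clearly beat chance, as they do on the real impacts.
    """

    grid_shape: tuple = (32, 32, 32)
    voxel_size: float = 2.0
    n_cases: int = 58
    n_concussion: int = 25
    planted_rois: tuple = ("SLF-R", "EC-L")
    effect_size: float = 3.0  # class separation of planted-ROI mean strain, in within-class SDs
    correlation_length: float = 2.0  # voxels, Gaussian kernel width of the noise field
    severity_spread: float = 0.4  # SD of log latent severity
    attenuation_range: tuple = (0.5, 0.9)  # fiber/MPS ratio bounds
    kinematics_coupling: float = 0.7  # corr. of log peak angular speed with log severity
    baseline_strain: float = 0.08  # median MPS of the smooth baseline pattern
    kin_scale: float = 22.0  # median peak angular speed, rad/s
    kin_spread: float = 0.35  # SD of log peak angular speed
    seed: int = 0
    max_label_attempts: int = 5000

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.planted_rois = tuple(self.planted_rois)
        lo, hi = self.attenuation_range
        if not (0 < lo <= hi <= 1):
            raise GenerationError("attenuation_range must lie within (0, 1]")
        if not (0 < self.n_concussion < self.n_cases):
            raise GenerationError("need 0 < n_concussion < n_cases")
        if self.effect_size < 0:
            raise GenerationError("effect_size must be >= 0")
        if not (0.0 <= self.kinematics_coupling <= 1.0):
            raise GenerationError("kinematics_coupling must be in [0, 1]")
        for name in self.planted_rois:
            if name not in ROI_LABELS or ROI_LABELS[name] == 0:
                raise GenerationError(f"unknown planted ROI {name!r}")


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #
# ROI blob centers/radii in normalized coordinates ([-1, 1] per axis;
# x = posterior-anterior, y = right-left, z = inferior-superior).
_ROI_BLOBS = {
    "CC": ((0.00, 0.00, 0.12), 0.15),
    "SLF-R": ((0.05, -0.33, 0.22), 0.14),
    "SLF-L": ((0.05, 0.33, 0.22), 0.14),
    "EC-L": ((0.00, 0.40, 0.00), 0.13),
    "EC-R": ((0.00, -0.40, 0.00), 0.13),
    "brainstem": ((-0.08, 0.00, -0.42), 0.15),
}
_BRAIN_RADII = (0.88, 0.80, 0.84)
_WM_SCALE = 0.72


def _normalized_coords(shape):
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    return np.meshgrid(*axes, indexing="ij")


def make_grid(config: GeneratorConfig) -> VolumeGrid:
    """Build the shared grid: smoothed-ellipsoid brain/WM masks + ROI blobs."""
    shape = config.grid_shape
    if len(shape) != 3 or min(shape) < 8:
        raise GenerationError("grid_shape must be 3 axes of at least 8 voxels")
    rng = np.random.default_rng(derive_seed(config.seed, "grid"))
    xx, yy, zz = _normalized_coords(shape)

    # smooth multiplicative wobble so masks are not perfect ellipsoids
    wobble = gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 8.0)
    wobble = wobble / (np.abs(wobble).max() + 1e-12)

    def ellipsoid(radii, scale=1.0, amp=0.06):
        q = (
            (xx / (scale * radii[0])) ** 2
            + (yy / (scale * radii[1])) ** 2
            + (zz / (scale * radii[2])) ** 2
        )
        return q <= 1.0 + amp * wobble

    brain = ellipsoid(_BRAIN_RADII)
    wm = ellipsoid(_BRAIN_RADII, scale=_WM_SCALE) & brain

    labels = np.zeros(shape, dtype=np.int8)
    for name, (center, radius) in _ROI_BLOBS.items():
        blob = (
            (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
        ) <= radius**2
        blob &= wm & (labels == 0)
        if np.count_nonzero(blob) < 4:
            raise GenerationError(
                f"grid {shape} too small to fit 7 disjoint ROIs (ROI {name} "
                f"has {np.count_nonzero(blob)} voxels)"
            )
        labels[blob] = ROI_LABELS[name]
    rest = wm & (labels == 0)
    if not rest.any():
        raise GenerationError("no other-WM voxels left after placing ROI blobs")
    labels[rest] = ROI_LABELS["other-WM"]
    return VolumeGrid(roi_labels=labels, brain_mask=brain, voxel_size=config.voxel_size)


# --------------------------------------------------------------------------- #
# strain fields and labels
# --------------------------------------------------------------------------- #
def _smooth_unit_field(rng, shape, sigma):
    """Standardized Gaussian-smoothed white noise (mean 0, SD 1)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _draw_labels(rng, z, n_pos, effect_size, max_attempts):
    """Labels from a logistic law on the standardized planted-ROI mean.

    The intercept is calibrated by bisection so the expected prevalence
    matches n_pos / n, then draws are rejection-resampled until the class
    counts are exact.
    """
    n = z.size
    target = n_pos / n
    beta = float(effect_size)
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expit(mid + beta * z).mean() < target:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    probs = expit(alpha + beta * z)
    for attempt in range(1, max_attempts + 1):
        y = (rng.random(n) < probs).astype(int)
        if y.sum() == n_pos:
            return y, attempt
    raise GenerationError(
        f"label rejection sampling failed to reach {n_pos}/{n} concussions in "
        f"{max_attempts} attempts (mean acceptance prob {probs.mean():.3f})"
    )


def _pooled_within_sd(m, y):
    m1, m0 = m[y == 1], m[y == 0]
    n1, n0 = m1.size, m0.size
    var = ((n1 - 1) * m1.var(ddof=1) + (n0 - 1) * m0.var(ddof=1)) / (n1 + n0 - 2)
    return float(np.sqrt(var))


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate a complete synthetic dataset with ground truth in provenance."""
    grid = make_grid(config)
    rng = np.random.default_rng(derive_seed(config.seed, "cases"))
    shape = config.grid_shape
    n = config.n_cases

    # fixed smooth baseline strain pattern, strictly positive
    baseline = config.baseline_strain * np.exp(
        0.4 * _smooth_unit_field(rng, shape, sigma=max(shape) / 8.0)
    )

    severities = np.exp(config.severity_spread * rng.standard_normal(n))

    planted_feat = np.concatenate(
        [grid.roi_feature_indices(name) for name in config.planted_rois]
    )
    planted_feat = np.unique(planted_feat)
    planted_vol = np.isin(grid.roi_labels, [ROI_LABELS[r] for r in config.planted_rois])

    brain = grid.brain_mask
    wm = grid.wm_mask
    fibers, mpss = [], []
    for i in range(n):
        field3d = np.exp(0.35 * _smooth_unit_field(rng, shape, config.correlation_length))
        mps = severities[i] * baseline * field3d
        mps[~brain] = 0.0
        atten = rng.uniform(*config.attenuation_range, size=shape)
        fiber = mps * atten
        fiber[~wm] = 0.0
        fibers.append(fiber)
        mpss.append(mps)

    # planted-ROI mean fiber strain drives the labels
    m = np.array([grid.flatten(f)[planted_feat].mean() for f in fibers])
    z = (m - m.mean()) / (m.std() + 1e-12)
    labels, attempts = _draw_labels(
        rng, z, config.n_concussion, config.effect_size, config.max_label_attempts
    )

    # calibrate the realized standardized separation to effect_size by lifting
    # the concussed cases' planted-ROI strains (a per-case multiplicative
    # factor shifts each case's regional mean by the same additive delta, so
    # within-class SDs are unchanged and the target is hit exactly)
    if config.effect_size > 0:
        sd_w = _pooled_within_sd(m, labels)
        achieved = (m[labels == 1].mean() - m[labels == 0].mean()) / sd_w
        delta = (config.effect_size - achieved) * sd_w
        for i in np.flatnonzero(labels == 1):
            factor = max((m[i] + delta) / m[i], 0.05)
            fibers[i][planted_vol] *= factor
            mpss[i][planted_vol] *= factor
            m[i] = grid.flatten(fibers[i])[planted_feat].mean()

    # kinematics: log peak angular speed couples to log severity
    zs = np.log(severities)
    zs = (zs - zs.mean()) / (zs.std() + 1e-12)
    kappa = config.kinematics_coupling
    g = kappa * zs + np.sqrt(max(1.0 - kappa**2, 0.0)) * rng.standard_normal(n)
    speed = config.kin_scale * np.exp(config.kin_spread * g)
    direction = np.abs(rng.standard_normal((n, 3)))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    omega = speed[:, None] * direction

    cases = [
        StrainCase(
            case_id=f"case{i:03d}",
            fiber_strain=fibers[i],
            mps=mpss[i],
            peak_ang_vel=omega[i],
            label=int(labels[i]),
        )
        for i in range(n)
    ]
    truth = {
        "planted_feature_indices": planted_feat.tolist(),
        "planted_rois": list(config.planted_rois),
        "severities": severities.tolist(),
        "label_draw_attempts": attempts,
        "realized_separation": float(
            (m[labels == 1].mean() - m[labels == 0].mean())
            / _pooled_within_sd(m, labels)
        ),
    }
    ds = Dataset(
        grid=grid,
        cases=cases,
        provenance={
            "generator": "strainclass.synthetic",
            "config": asdict(config),
            "seed": config.seed,
            "ground_truth": truth,
        },
    )
    ds.validate()
    return ds


def ground_truth(config: GeneratorConfig, dataset: Dataset) -> dict:
    """Planted voxel indices and per-case latent severities of a generated set."""
    prov = dataset.provenance
    if prov.get("generator") != "strainclass.synthetic" or "ground_truth" not in prov:
        raise GenerationError("dataset was not produced by this generator")
    truth = dict(prov["ground_truth"])
    truth["planted_feature_indices"] = np.asarray(
        truth["planted_feature_indices"], dtype=int
    )
    truth["severities"] = np.asarray(truth["severities"], dtype=float)
    return truth


def write_synthetic_dataset(config: GeneratorConfig, directory) -> Path:
    """Generate and write a dataset directory with ground-truth + config sidecars."""
    directory = Path(directory)
    ds = generate_dataset(config)
    manifest = write_dataset(ds, directory)
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(ds.provenance["ground_truth"], fh, indent=1)
    with open(directory / "generator_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1)
    return manifest
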