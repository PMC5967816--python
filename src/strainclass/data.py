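"""Strain cases, datasets and NIfTI/manifest I/O.

A :class:`StrainCase` is one simulated head impact: a peak fiber-strain
volume and a peak maximum-principal-strain (MPS) volume on the shared grid,
the per-axis peak angular-velocity magnitudes (rad/s), and the binary injury
label (1 = concussion). Datasets are stored on disk as one NIfTI per volume
plus a CSV manifest with columns

    case_id,label,wx,wy,wz,fiber_path,mps_path

next to the grid bundle (``brain_mask.nii.gz`` + ``roi_labels.nii.gz``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridError, VolumeGrid

__all__ = [
    "StrainCase",
    "Dataset",
    "DataError",
    "read_volume",
    "write_volume",
    "flatten_wm",
    "unflatten_wm",
    "read_manifest",
    "write_dataset",
]

MANIFEST_COLUMNS = ["case_id", "label", "wx", "wy", "wz", "fiber_path", "mps_path"]


class DataError(ValueError):
    """Raised for invalid cases, datasets or manifests."""


# --------------------------------------------------------------------------- #
# volume I/O
# --------------------------------------------------------------------------- #
def read_volume(path, grid: VolumeGrid | None = None):
    """Read a 3D NIfTI volume.

    Returns ``(array, meta)`` where ``meta`` carries the affine and voxel
    size. If ``grid`` is given the volume shape must match it.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DataError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    if grid is not None and data.shape != grid.shape:
        raise DataError(
            f"{path}: volume shape {data.shape} does not match grid {grid.shape}"
        )
    meta = {
        "affine": np.asarray(img.affine),
        "voxel_size": tuple(float(z) for z in img.header.get_zooms()[:3]),
    }
    return data, meta


def write_volume(path, array: np.ndarray, grid: VolumeGrid | None = None) -> None:
    """Write a 3D volume as 32-bit float NIfTI (standard for strain ~O(0.1))."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise DataError("write_volume expects a 3D array")
    affine = grid.affine if grid is not None else np.eye(4)
    nib.save(nib.Nifti1Image(array.astype(np.float32), affine), str(path))


# --------------------------------------------------------------------------- #
# cases
# --------------------------------------------------------------------------- #
@dataclass
class StrainCase:
    """One impact: strain volumes, kinematics, injury label."""

    case_id: str
    fiber_strain: np.ndarray
    mps: np.ndarray
    peak_ang_vel: np.ndarray  # (3,) per-axis peak angular-velocity magnitude, rad/s
    label: int  # 1 = concussion, 0 = non-injury

    def __post_init__(self):
        self.fiber_strain = np.asarray(self.fiber_strain, dtype=np.float64)
        self.mps = np.asarray(self.mps, dtype=np.float64)
        self.peak_ang_vel = np.asarray(self.peak_ang_vel, dtype=np.float64).reshape(3)
        self.label = int(self.label)
        if self.label not in (0, 1):
            raise DataError(f"{self.case_id}: label must be 0 or 1")

    def validate(self, grid: VolumeGrid, atol: float = 1e-6) -> None:
        """Enforce the structural invariants of a strain-encoded case."""
        for name, vol in (("fiber_strain", self.fiber_strain), ("mps", self.mps)):
            if vol.shape != grid.shape:
                raise DataError(f"{self.case_id}: {name} shape mismatch with grid")
            if np.any(vol < -atol):
                raise DataError(f"{self.case_id}: negative {name} values")
        if np.any(np.abs(self.fiber_strain[~grid.wm_mask]) > atol):
            raise DataError(
                f"{self.case_id}: fiber strain nonzero outside the WM mask "
                "(volumes must be zero-padded outside WM)"
            )
        if np.any(np.abs(self.mps[~grid.brain_mask]) > atol):
            raise DataError(f"{self.case_id}: MPS nonzero outside the brain mask")
        # fiber strain is a projection of the strain tensor, so it cannot
        # exceed the maximum principal strain anywhere
        if np.any(self.fiber_strain > self.mps + atol):
            raise DataError(f"{self.case_id}: fiber strain exceeds MPS")
        if np.any(self.peak_ang_vel < 0):
            raise DataError(f"{self.case_id}: negative peak angular velocity")


def flatten_wm(case: StrainCase, grid: VolumeGrid) -> np.ndarray:
    """Fiber-strain feature vector (length ``grid.n_wm``) in canonical order.

    This is the raw input signal for the feature-based classifiers.
    """
    return grid.flatten(case.fiber_strain)


def unflatten_wm(vector: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Inverse of :func:`flatten_wm`; zeros outside WM."""
    return grid.unflatten(vector, fill=0.0)


# --------------------------------------------------------------------------- #
# datasets
# --------------------------------------------------------------------------- #
@dataclass
class Dataset:
    """All cases of one study on a shared grid."""

    grid: VolumeGrid
    cases: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate case_id(s): {dupes}")
        labels = {c.label for c in self.cases}
        if labels != {0, 1}:
            raise DataError("dataset must contain both concussion and non-injury cases")

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases], dtype=int)

    @property
    def case_ids(self) -> list:
        return [c.case_id for c in self.cases]

    @property
    def class_counts(self) -> tuple:
        """(n_concussion, n_non_injury)."""
        y = self.labels
        return int((y == 1).sum()), int((y == 0).sum())

    def feature_matrix(self) -> np.ndarray:
        """Case x WM-voxel matrix of fiber strains (classifier input)."""
        return np.stack([flatten_wm(c, self.grid) for c in self.cases])

    def kinematics(self) -> np.ndarray:
        return np.stack([c.peak_ang_vel for c in self.cases])

    def validate(self) -> None:
        for c in self.cases:
            c.validate(self.grid)


def write_dataset(dataset: Dataset, directory) -> Path:
    """Write grid bundle, per-case NIfTI volumes and the CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.grid.save(directory)
    rows = []
    for c in dataset.cases:
        fiber = f"{c.case_id}_fiber.nii.gz"
        mps = f"{c.case_id}_mps.nii.gz"
        write_volume(directory / fiber, c.fiber_strain, dataset.grid)
        write_volume(directory / mps, c.mps, dataset.grid)
        rows.append(
            {
                "case_id": c.case_id,
                "label": c.label,
                "wx": c.peak_ang_vel[0],
                "wy": c.peak_ang_vel[1],
                "wz": c.peak_ang_vel[2],
                "fiber_path": fiber,
                "mps_path": mps,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        directory / "manifest.csv", index=False
    )
    return directory / "manifest.csv"


def read_manifest(path, grid: VolumeGrid | None = None) -> Dataset:
    """Read a manifest CSV (or JSON) and load a fully validated Dataset.

    The grid bundle is expected next to the manifest unless ``grid`` is
    passed explicitly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        table = pd.read_json(path)
    else:
        table = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"manifest missing columns: {missing}")
    if grid is None:
        try:
            grid = VolumeGrid.load(path.parent)
        except FileNotFoundError as exc:
            raise DataError(f"grid bundle not found next to manifest: {exc}") from exc

    cases = []
    for row in table.itertuples(index=False):
        fiber_path = path.parent / str(row.fiber_path)
        mps_path = path.parent / str(row.mps_path)
        for p in (fiber_path, mps_path):
            if not p.exists():
                raise DataError(f"volume file missing: {p}")
        fiber, _ = read_volume(fiber_path, grid)
        mps, _ = read_volume(mps_path, grid)
        cases.append(
            StrainCase(
                case_id=str(row.case_id),
                fiber_strain=fiber,
                mps=mps,
                peak_ang_vel=np.array([row.wx, row.wy, row.wz], dtype=float),
                label=int(row.label),
            )
        )
    ds = Dataset(grid=grid, cases=cases, provenance={"manifest": str(path)})
    ds.validate()
    return ds
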