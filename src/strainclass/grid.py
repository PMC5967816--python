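"""Shared voxel grid: white-matter mask, ROI labels and canonical voxel order.

All cases in a dataset live on one grid (the strain fields come from a single
head model, so volumes are voxel-aligned by construction; no registration is
performed). Feature vectors are indexed by a fixed linear enumeration of the
WM voxels so that voxel i means the same anatomical location in every fold,
case and selection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ROI_LABELS",
    "ROI_NAMES",
    "VolumeGrid",
    "GridError",
]

# ROI label conventions. 0 is non-WM background; 7 collects WM voxels not
# belonging to a named tract.
ROI_LABELS = {
    "non-WM": 0,
    "CC": 1,
    "SLF-R": 2,
    "SLF-L": 3,
    "EC-L": 4,
    "EC-R": 5,
    "brainstem": 6,
    "other-WM": 7,
}
ROI_NAMES = {v: k for k, v in ROI_LABELS.items()}


class GridError(ValueError):
    """Raised for grid/volume inconsistencies (shape mismatch, bad masks)."""


@dataclass
class VolumeGrid:
    """3D voxel grid with brain/WM masks and ROI labels.

    Parameters
    ----------
    roi_labels : int array, shape ``shape``
        Per-voxel ROI label (see :data:`ROI_LABELS`). Every label > 0 voxel
        is a WM voxel; the WM mask is exactly ``roi_labels > 0``.
    brain_mask : bool array, shape ``shape``
        Superset of the WM mask (the region where maximum principal strain
        is defined).
    voxel_size : float or 3-tuple, mm.
    """

    roi_labels: np.ndarray
    brain_mask: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.0)
    # Canonical voxel order: ascending linear index with the x axis fastest
    # (Fortran ravel order) restricted to WM voxels.
    _wm_flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.roi_labels = np.asarray(self.roi_labels)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.roi_labels.ndim != 3:
            raise GridError("roi_labels must be a 3D volume")
        if self.brain_mask.shape != self.roi_labels.shape:
            raise GridError("brain_mask and roi_labels shapes differ")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if not np.issubdtype(self.roi_labels.dtype, np.integer):
            raise GridError("roi_labels must be integer-valued")
        if self.roi_labels.min() < 0 or self.roi_labels.max() > 7:
            raise GridError("roi_labels outside the 0..7 label set")
        wm = self.roi_labels > 0
        if not wm.any():
            raise GridError("grid has no WM voxels")
        if np.any(wm & ~self.brain_mask):
            raise GridError("WM mask must be a subset of the brain mask")
        self._wm_flat = np.flatnonzero(wm.ravel(order="F"))

    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> tuple:
        return self.roi_labels.shape

    @property
    def wm_mask(self) -> np.ndarray:
        return self.roi_labels > 0

    @property
    def n_wm(self) -> int:
        """Number of WM voxels = feature-vector length."""
        return int(self._wm_flat.size)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    # ------------------------------------------------------------------ #
    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract the WM voxels of ``volume`` in canonical order."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise GridError(
                f"volume shape {volume.shape} does not match grid {self.shape}"
            )
        return volume.ravel(order="F")[self._wm_flat]

    def unflatten(self, vector: np.ndarray, fill=0.0) -> np.ndarray:
        """Place a WM feature vector back on the grid, ``fill`` elsewhere."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_wm,):
            raise GridError(
                f"vector length {vector.shape} does not match N_WM={self.n_wm}"
            )
        flat = np.full(int(np.prod(self.shape)), fill, dtype=float)
        flat[self._wm_flat] = vector
        return flat.reshape(self.shape, order="F")

    def roi_mask(self, label) -> np.ndarray:
        """Boolean volume of one ROI. ``label`` may be an int or an ROI name."""
        if isinstance(label, str):
            label = ROI_LABELS[label]
        label = int(label)
        if label not in ROI_NAMES:
            raise GridError(f"unknown ROI label {label}")
        mask = self.roi_labels == label
        if not mask.any():
            raise GridError(f"ROI {ROI_NAMES[label]} ({label}) is empty")
        return mask

    def roi_feature_indices(self, label) -> np.ndarray:
        """Canonical feature indices of one ROI's voxels."""
        flat = self.flatten(self.roi_mask(label).astype(np.int8))
        return np.flatnonzero(flat > 0)

    def label_census(self) -> dict:
        """Voxel count per ROI name (WM labels only)."""
        return {
            name: int(np.count_nonzero(self.roi_labels == lab))
            for name, lab in ROI_LABELS.items()
            if lab > 0
        }

    # ------------------------------------------------------------------ #
    def save(self, directory) -> None:
        """Write the grid bundle: brain-mask NIfTI + ROI-label NIfTI."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.brain_mask.astype(np.int8), self.affine),
            directory / "brain_mask.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(self.roi_labels.astype(np.int8), self.affine),
            directory / "roi_labels.nii.gz",
        )

    @classmethod
    def load(cls, directory) -> "VolumeGrid":
        directory = Path(directory)
        brain = nib.load(directory / "brain_mask.nii.gz")
        labels = nib.load(directory / "roi_labels.nii.gz")
        voxel_size = tuple(float(z) for z in brain.header.get_zooms()[:3])
        return cls(
            roi_labels=np.asarray(labels.dataobj).astype(np.int8),
            brain_mask=np.asarray(brain.dataobj).astype(bool),
            voxel_size=voxel_size,
        )
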