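"""Core in-memory containers: scalar image volumes, ROI masks, discretized VOIs.

Arrays are indexed ``(z, y, x)`` with ``spacing_mm = (dz, dy, dx)``; the axial
(slice) axis is axis 0, matching the PET convention of thick axial planes
(e.g. 0.98 x 0.98 x 3 mm voxels carried as spacing (3, 0.98, 0.98)).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "ROIMask", "DiscretizedVOI", "load_volume", "load_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar field with voxel spacing.

    ``values`` holds SUV (g/mL) or activity (Bq/mL) depending on pipeline
    stage; units are the caller's contract.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy_with(self, values: np.ndarray) -> "ImageVolume":
        return ImageVolume(values, self.spacing_mm, self.origin_mm)


@dataclass
class ROIMask:
    """Binary 3D mask aligned to an :class:`ImageVolume` grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())


@dataclass
class DiscretizedVOI:
    """Integer grey levels 1..D on mask voxels; the input to texture matrices.

    ``grey`` is 0 outside the mask, 1..D inside.  The grey axis of every
    texture matrix built from this VOI always spans the full 1..D range so
    per-slice matrices stay conformable for merging.
    """

    grey: np.ndarray
    mask: np.ndarray
    n_bins: int
    suv_min: float
    suv_max: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.grey = np.asarray(self.grey, dtype=np.int32)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.grey.shape != self.mask.shape:
            raise ValueError("grey and mask shapes differ")
        if self.mask.any():
            inside = self.grey[self.mask]
            if inside.min() < 1 or inside.max() > self.n_bins:
                raise ValueError("grey levels must lie in 1..D on mask voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def load_volume(path: str) -> ImageVolume:
    """Read a NIfTI volume; reorders nibabel's (x, y, z) data to (z, y, x)."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageVolume(data, spacing)


def load_mask(path: str) -> ROIMask:
    img = nib.load(path)
    data = np.asarray(img.dataobj).transpose(2, 1, 0) > 0.5
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ROIMask(data, spacing)


def save_volume(vol: ImageVolume | ROIMask, path: str) -> None:
    """Write as NIfTI with an affine encoding the voxel spacing."""
    data = np.asarray(vol.values)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    dz, dy, dx = vol.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data.transpose(2, 1, 0), affine), path)
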