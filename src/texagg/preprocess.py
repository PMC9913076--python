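"""PET preprocessing: SUV conversion, resampling, mask algebra, partial volume
correction and fixed-bin-number (FBN) discretization.

The pipeline order mirrors the study design: observer-mask intersection ->
body-weight SUV -> (optional) Van Cittert deconvolution -> FBN discretization
inside the VOI -> texture matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import DiscretizedVOI, ImageVolume, ROIMask

log = logging.getLogger(__name__)

__all__ = [
    "PVCConfig",
    "compute_suv",
    "resample_cubic",
    "mask_intersection",
    "dice",
    "van_cittert",
    "gaussian_kernel_1d",
    "discretize_fbn",
    "matv",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class EmptyROIError(ValueError):
    """Raised when an operation needs a nonempty ROI and gets none."""


@dataclass
class PVCConfig:
    """Van Cittert deconvolution settings.

    ``alpha`` is the order-1 convergence step, ``psf_fwhm_mm`` the full width
    at half maximum of the scanner point-spread function modelled as an
    isotropic 3D Gaussian (in millimetres).
    """

    psf_fwhm_mm: float
    alpha: float = 1.0
    n_iterations: int = 10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.psf_fwhm_mm <= 0:
            raise ValueError("psf_fwhm_mm must be > 0")


def compute_suv(activity: ImageVolume, injected_dose_bq: float, body_weight_g: float) -> ImageVolume:
    """Body-weight SUV: tissue activity (Bq/mL) / (injected dose (Bq) / body weight (g)).

    Activity is assumed already decay-corrected to acquisition time.
    """
    if injected_dose_bq <= 0:
        raise ValueError("injected dose must be > 0")
    if body_weight_g <= 0:
        raise ValueError("body weight must be > 0")
    return activity.copy_with(activity.values * (body_weight_g / injected_dose_bq))


def mask_intersection(a: ROIMask, b: ROIMask) -> ROIMask:
    """Voxelwise AND of two delineations; errors on an empty intersection."""
    if a.shape != b.shape:
        raise ValueError("masks are not aligned")
    both = a.values & b.values
    if not both.any():
        raise EmptyROIError("observer masks do not overlap")
    return ROIMask(both, a.spacing_mm)


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice similarity coefficient 2|a&b| / (|a|+|b|)."""
    if a.shape != b.shape:
        raise ValueError("masks are not aligned")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise EmptyROIError("Dice undefined for two empty masks")
    return 2.0 * float(np.count_nonzero(a.values & b.values)) / (na + nb)


def gaussian_kernel_1d(sigma_vox: float, truncate: float = 3.0) -> np.ndarray:
    """Discrete Gaussian, truncated at +-truncate*sigma, renormalized to sum 1."""
    radius = max(1, int(math.ceil(truncate * sigma_vox)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()


def _psf_convolve(values: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    out = values
    for axis, k in enumerate(kernels):
        if len(k) > values.shape[axis] * 2 - 1:
            raise ValueError("PSF kernel larger than volume along axis %d" % axis)
        out = ndimage.convolve1d(out, k, axis=axis, mode="reflect")
    return out


def van_cittert(
    suv0: ImageVolume,
    cfg: PVCConfig,
    kernels: list[np.ndarray] | None = None,
) -> ImageVolume:
    """Iterative Van Cittert deconvolution.

    SUV(i) = SUV(i-1) + alpha * (SUV(0) - psf (x) SUV(i-1)), clamped to >= 0
    after every iteration (voxel values must stay non-negative).  The PSF is a
    normalized separable 3D Gaussian built from ``psf_fwhm_mm`` and the voxel
    spacing; ``kernels`` overrides it with explicit per-axis 1D kernels
    (used by the tests to inject delta / hand kernels).
    """
    if kernels is None:
        sigma_mm = cfg.psf_fwhm_mm * _FWHM_TO_SIGMA
        kernels = [gaussian_kernel_1d(sigma_mm / s) for s in suv0.spacing_mm]
    est = suv0.values.astype(np.float64)
    ref = est.copy()
    for _ in range(cfg.n_iterations):
        est = est + cfg.alpha * (ref - _psf_convolve(est, kernels))
        np.maximum(est, 0.0, out=est)
    return suv0.copy_with(est)


def resample_cubic(volume: ImageVolume, target_spacing_mm: tuple[float, float, float]) -> ImageVolume:
    """Tricubic spline interpolation onto a grid with the target spacing.

    The new grid covers the same physical extent (voxel-center aligned at the
    origin corner).  Axes with fewer than 4 planes fall back to linear
    interpolation (cubic splines need 4 support points), which is logged.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be strictly positive")
    if target == volume.spacing_mm:
        return volume.copy_with(volume.values.copy())
    new_shape = [
        max(1, int(round(n * src / dst)))
        for n, src, dst in zip(volume.shape, volume.spacing_mm, target)
    ]
    coords = np.meshgrid(
        *[
            np.arange(m, dtype=float) * dst / src
            for m, src, dst in zip(new_shape, volume.spacing_mm, target)
        ],
        indexing="ij",
    )
    order = 3
    degenerate = [ax for ax, n in enumerate(volume.shape) if n < 4]
    if degenerate:
        order = 1
        log.warning(
            "resample_cubic: axes %s have <4 planes; falling back to linear", degenerate
        )
    out = ndimage.map_coordinates(
        volume.values.astype(np.float64), np.stack(coords), order=order, mode="reflect"
    )
    return ImageVolume(out, target, volume.origin_mm)


def resample_mask_nearest(mask: ROIMask, target_spacing_mm: tuple[float, float, float]) -> ROIMask:
    """Nearest-neighbour mask resampling (preserves binarity)."""
    target = tuple(float(s) for s in target_spacing_mm)
    if target == mask.spacing_mm:
        return ROIMask(mask.values.copy(), target)
    new_shape = [
        max(1, int(round(n * src / dst)))
        for n, src, dst in zip(mask.shape, mask.spacing_mm, target)
    ]
    idx = np.ix_(
        *[
            np.clip(np.round(np.arange(m) * dst / src).astype(int), 0, n - 1)
            for m, n, src, dst in zip(new_shape, mask.shape, mask.spacing_mm, target)
        ]
    )
    return ROIMask(mask.values[idx], target)


def discretize_fbn(suv: ImageVolume, mask: ROIMask, n_bins: int) -> DiscretizedVOI:
    """Fixed-bin-number discretization of the VOI into grey levels 1..D.

    Voxels at the VOI minimum get grey 1; otherwise
    ``grey = ceil(D * (SUV - SUVmin) / (SUVmax - SUVmin))`` so the VOI maximum
    maps to D.  SUVmin/SUVmax are taken over mask voxels only.  A constant VOI
    degenerates to all grey 1 (logged).
    """
    if n_bins < 2:
        raise ValueError("FBN needs at least 2 bins")
    if suv.shape != mask.shape:
        raise ValueError("volume and mask are not aligned")
    if mask.is_empty():
        raise EmptyROIError("cannot discretize an empty VOI")
    inside = suv.values[mask.values]
    lo, hi = float(inside.min()), float(inside.max())
    grey = np.zeros(suv.shape, dtype=np.int32)
    if hi == lo:
        log.warning("discretize_fbn: constant VOI (SUVmin == SUVmax); all grey 1")
        grey[mask.values] = 1
    else:
        scaled = np.ceil(n_bins * (suv.values[mask.values] - lo) / (hi - lo))
        grey[mask.values] = np.clip(scaled, 1, n_bins).astype(np.int32)
    return DiscretizedVOI(grey, mask.values, n_bins, lo, hi, suv.spacing_mm)


def matv(mask: ROIMask, spacing_mm: tuple[float, float, float] | None = None) -> float:
    """Metabolically active tumor volume in mL (voxel count x voxel volume)."""
    sp = mask.spacing_mm if spacing_mm is None else tuple(float(s) for s in spacing_mm)
    return mask.n_voxels * float(np.prod(sp)) / 1000.0
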