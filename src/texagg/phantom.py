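"""Synthetic FDG-PET phantom cohorts with textured lesions and paired observer masks.

The generator emulates the statistics of a clinical head-and-neck PET cohort:
lesion volumes from a lognormal calibrated to MATV 50.9 +/- 86.4 mL, peak
uptake from a lognormal calibrated to SUVmax 15.4 +/- 7.77 g/mL, anisotropic
voxels (3 x 0.98 x 0.98 mm after interpolation to the CT grid), injected dose
uniform over 306-468 MBq, and a second observer delineation perturbed toward a
median Dice of 0.87.  Each patient carries a single ellipsoidal lesion whose
interior is a radial uptake profile plus a spatially correlated Gaussian
random field, so that every texture-matrix family sees non-degenerate
grey-level structure.  No scanner physics is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize, special

from .image import DiscretizedVOI, ImageVolume, ROIMask, save_volume
from .preprocess import dice

__all__ = [
    "PhantomParams",
    "SyntheticPatient",
    "generate_cohort",
    "fixture_grid",
    "write_cohort",
    "lognormal_params",
    "reduced_params",
]

MBQ = 1.0e6  # Bq per MBq


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and standard deviation."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class PhantomParams:
    """Cohort-level generator settings; the defaults are the study conditions."""

    n_patients: int = 128
    seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 128, 128)
    spacing_mm: tuple[float, float, float] = (3.0, 0.98, 0.98)
    #: (mu, sigma) of the lesion-volume lognormal in mL (mean 50.9, SD 86.4)
    lesion_volume_lognormal: tuple[float, float] = lognormal_params(50.9, 86.4)
    suv_background: float = 1.0
    suv_lesion_mean: float = 7.95
    suv_lesion_max_target: float = 15.4
    suv_lesion_max_sd: float = 7.77
    texture_correlation_length_mm: float = 8.0
    texture_amplitude: float = 0.35
    observer_dice_target: float = 0.87
    observer_dice_sd: float = 0.02
    dose_range_bq: tuple[float, float] = (306.0 * MBQ, 468.0 * MBQ)
    body_weight_mean_g: float = 60_000.0
    body_weight_sd_g: float = 10_000.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        for name in (
            "suv_background",
            "suv_lesion_mean",
            "suv_lesion_max_target",
            "texture_correlation_length_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.observer_dice_target <= 1.0):
            raise ValueError("observer_dice_target must be in (0, 1]")


def reduced_params(n_patients: int = 128, seed: int = 0) -> PhantomParams:
    """Desk-scale study conditions: 48^3 grids with proportionally smaller lesions.

    Lesion volume statistics are scaled so the cohort fits the small grid
    while keeping the heavy right skew of the clinical distribution.
    """
    return PhantomParams(
        n_patients=n_patients,
        seed=seed,
        grid_shape=(48, 48, 48),
        lesion_volume_lognormal=lognormal_params(8.0, 6.0),
    )


@dataclass
class SyntheticPatient:
    patient_id: str
    activity_volume: ImageVolume  # Bq/mL, decay-corrected
    injected_dose_bq: float
    body_weight_g: float
    mask_observer1: ROIMask
    mask_observer2: ROIMask


class LesionSizingError(ValueError):
    """Raised when the configured lesion distribution cannot fit the grid."""


def _radial_exponent(params: PhantomParams) -> float:
    """Profile exponent gamma of (1 - q)^gamma matching the lesion mean/max ratio.

    For an ellipsoid, the spatial mean of (1 - q)^gamma (q the normalized
    quadratic form) is 1.5 * B(3/2, gamma + 1).
    """
    target = (params.suv_lesion_mean - params.suv_background) / (
        params.suv_lesion_max_target - params.suv_background
    )
    target = min(max(target, 0.05), 0.95)

    def mean_ratio(g: float) -> float:
        return 1.5 * special.beta(1.5, g + 1.0)

    return float(optimize.brentq(lambda g: mean_ratio(g) - target, 1e-3, 50.0))


def _grid_capacity_ml(params: PhantomParams) -> float:
    """Largest isotropic lesion volume (mL) that fits the grid with margins."""
    spacing = np.asarray(params.spacing_mm)
    extent = np.asarray(params.grid_shape) * spacing
    r_max = float(np.min((extent - 8.0 * spacing) / 2.0))
    return max(4.0 / 3.0 * math.pi * r_max**3 / 1000.0, 1e-3)


def _truncation_corrected_mu(params: PhantomParams, mu: float, sigma: float) -> float:
    """Shift the volume lognormal so its grid-truncated mean matches the
    configured (untruncated) mean.

    Oversize draws are resampled, which biases the realized mean downward;
    this solves E[V | V < capacity] = exp(mu + sigma^2/2) for the shifted mu.
    """
    cap = _grid_capacity_ml(params)
    target = math.exp(mu + sigma**2 / 2.0)
    if cap <= target:  # grid too tight to correct; sizes will error out later
        return mu

    def trunc_mean(m: float) -> float:
        z = (math.log(cap) - m) / sigma
        below = special.ndtr(z)
        if below <= 1e-12:
            return cap
        return math.exp(m + sigma**2 / 2.0) * special.ndtr(z - sigma) / below

    try:
        return float(optimize.brentq(lambda m: trunc_mean(m) - target, mu, mu + 5.0))
    except ValueError:
        return mu


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Unit-variance Gaussian random field with the given smoothing scale."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (1 + int(np.argmax(sizes)))


def _perturb_mask(
    q_norm: np.ndarray,
    rng: np.random.Generator,
    sigma_vox,
    target_dice: float,
    base: np.ndarray,
) -> np.ndarray:
    """Second-observer mask: noisy level set of the ellipsoid, amplitude bisected
    toward the per-patient Dice target; single component with holes filled."""
    noise = _smooth_noise(rng, q_norm.shape, sigma_vox)

    def realize(a: float) -> np.ndarray:
        m = q_norm + a * noise <= 1.0
        if not m.any():
            return m
        m = _largest_component(m)
        return ndimage.binary_fill_holes(m)

    def dsc(m: np.ndarray) -> float:
        inter = np.count_nonzero(m & base)
        return 2.0 * inter / (np.count_nonzero(m) + np.count_nonzero(base))

    lo, hi = 0.0, 2.0
    # grow hi until the dice drops below target (or give up at a large amplitude)
    for _ in range(8):
        m = realize(hi)
        if not m.any() or dsc(m) < target_dice:
            break
        hi *= 2.0
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        m = realize(mid)
        if m.any() and dsc(m) >= target_dice:
            lo = mid
        else:
            hi = mid
    out = realize(lo)
    if not out.any():
        out = base.copy()
    return out


def generate_cohort(params: PhantomParams) -> list[SyntheticPatient]:
    """Generate the synthetic cohort; bit-identical for identical params."""
    gamma = _radial_exponent(params)
    mu_v, sg_v = params.lesion_volume_lognormal
    mu_v = _truncation_corrected_mu(params, mu_v, sg_v)
    mu_m, sg_m = lognormal_params(params.suv_lesion_max_target, params.suv_lesion_max_sd)
    mu_w, sg_w = lognormal_params(params.body_weight_mean_g, params.body_weight_sd_g)
    spacing = np.asarray(params.spacing_mm)
    shape = np.asarray(params.grid_shape)
    extent = shape * spacing
    margin = 2.0 * spacing  # keep lesions off the grid boundary

    children = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    cohort: list[SyntheticPatient] = []
    for p, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        # lesion geometry: volume draw + mild random anisotropy, resampled to fit
        for attempt in range(200):
            vol_ml = float(rng.lognormal(mu_v, sg_v))
            aspect = np.exp(rng.normal(0.0, 0.15, size=3))
            aspect /= aspect.prod() ** (1.0 / 3.0)
            r_mm = (3.0 * vol_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0) * aspect
            if np.all(2.0 * r_mm <= extent - 2.0 * margin):
                break
        else:
            raise LesionSizingError(
                f"lesion distribution does not fit grid {params.grid_shape} "
                f"at spacing {params.spacing_mm}"
            )
        lo_c = margin + r_mm
        hi_c = extent - margin - r_mm
        center = lo_c + rng.random(3) * (hi_c - lo_c)

        # bounding box (voxel indices) with room for observer dilation
        pad_vox = np.ceil(3.0 / spacing).astype(int) + 2
        lo_i = np.maximum(0, np.floor((center - r_mm) / spacing).astype(int) - pad_vox)
        hi_i = np.minimum(shape, np.ceil((center + r_mm) / spacing).astype(int) + pad_vox)
        coords = np.meshgrid(
            *[(np.arange(a, b) + 0.5) * s for a, b, s in zip(lo_i, hi_i, spacing)],
            indexing="ij",
        )
        q = sum(((c - cc) / rr) ** 2 for c, cc, rr in zip(coords, center, r_mm))
        mask_box = q <= 1.0
        if not mask_box.any():  # degenerate sub-voxel lesion: keep the center voxel
            mask_box[tuple(np.unravel_index(np.argmin(q), q.shape))] = True

        # uptake: radial profile plus correlated texture, rescaled to the peak draw
        suv_max = max(float(rng.lognormal(mu_m, sg_m)), params.suv_background + 1.0)
        sigma_vox = params.texture_correlation_length_mm / spacing
        noise = _smooth_noise(rng, q.shape, sigma_vox)
        profile = np.clip(1.0 - q, 0.0, None) ** gamma
        excess = np.clip(profile * (1.0 + params.texture_amplitude * noise), 0.0, None)
        peak = excess[mask_box].max()
        if peak <= 0:
            excess[mask_box] = 1.0
            peak = 1.0
        suv_box = params.suv_background + (suv_max - params.suv_background) * excess / peak
        suv = np.full(tuple(shape), params.suv_background, dtype=np.float32)
        box = tuple(slice(a, b) for a, b in zip(lo_i, hi_i))
        suv[box] = np.where(mask_box, suv_box, params.suv_background).astype(np.float32)

        mask1 = np.zeros(tuple(shape), dtype=bool)
        mask1[box] = mask_box

        # observer 2: perturbed delineation toward the per-patient Dice target
        if params.observer_dice_target >= 1.0:
            mask2 = mask1.copy()
        else:
            t = float(
                np.clip(
                    rng.normal(params.observer_dice_target, params.observer_dice_sd),
                    0.70,
                    0.97,
                )
            )
            m2_box = _perturb_mask(q, rng, 0.75 * sigma_vox, t, mask_box)
            mask2 = np.zeros(tuple(shape), dtype=bool)
            mask2[box] = m2_box

        dose = float(rng.uniform(*params.dose_range_bq))
        weight = float(rng.lognormal(mu_w, sg_w))
        activity = suv.astype(np.float64) * (dose / weight)
        cohort.append(
            SyntheticPatient(
                patient_id=f"P{p:03d}",
                activity_volume=ImageVolume(activity.astype(np.float32), params.spacing_mm),
                injected_dose_bq=dose,
                body_weight_g=weight,
                mask_observer1=ROIMask(mask1, params.spacing_mm),
                mask_observer2=ROIMask(mask2, params.spacing_mm),
            )
        )
    return cohort


def cohort_median_dice(cohort: list[SyntheticPatient]) -> float:
    return float(
        np.median([dice(p.mask_observer1, p.mask_observer2) for p in cohort])
    )


def write_cohort(cohort: list[SyntheticPatient], out_dir: str | Path, seed: int | None = None) -> Path:
    """Write NIfTI volume + two observer masks per patient and a TSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["patient_id\tdose_Bq\tweight_g\tseed"]
    for p in cohort:
        save_volume(p.activity_volume, str(out / f"{p.patient_id}_activity.nii.gz"))
        save_volume(p.mask_observer1, str(out / f"{p.patient_id}_mask1.nii.gz"))
        save_volume(p.mask_observer2, str(out / f"{p.patient_id}_mask2.nii.gz"))
        lines.append(f"{p.patient_id}\t{p.injected_dose_bq:.0f}\t{p.body_weight_g:.0f}\t{seed}")
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


# -- deterministic fixture grids ------------------------------------------------

def _voi_from_grid(grid: np.ndarray, n_bins: int) -> tuple[DiscretizedVOI, ROIMask]:
    grid = np.asarray(grid, dtype=np.int32)
    mask = grid > 0
    voi = DiscretizedVOI(grid, mask, n_bins, float(grid[mask].min()), float(grid[mask].max()))
    return voi, ROIMask(mask)


_FIXTURES = {
    "constant-3x3": lambda: _voi_from_grid(np.ones((1, 3, 3), int), 1),
    "row-112": lambda: _voi_from_grid(np.array([[[1, 1, 2]]]), 2),
    "two-slice-constant": lambda: _voi_from_grid(
        np.stack([np.full((2, 2), 1), np.full((2, 2), 2)]), 2
    ),
    "checkerboard-2x2": lambda: _voi_from_grid(np.array([[[1, 2], [2, 1]]]), 2),
    "single-voxel": lambda: _voi_from_grid(np.ones((1, 1, 1), int), 1),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture_grid(name: str) -> tuple[DiscretizedVOI, ROIMask]:
    """Hand-enumerable grey-level grids used by the oracle tests."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; catalogue: {sorted(_FIXTURES)}") from None
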