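"""End-to-end experiments: feature extraction over a cohort, pairwise and
overall ICC analyses, FBN / PVC sweeps, and the MATV correlation study.

Per-patient stage order: observer-mask intersection -> SUV conversion ->
optional Van Cittert PVC -> FBN discretization inside the VOI -> texture
matrices -> features.  Every run over all aggregation methods yields
6 x (25 + 16) + 3 x (16 + 16 + 5 + 17) = 408 feature-method series per
patient per configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import texmat
from .image import ImageVolume, ROIMask
from .phantom import PhantomParams, SyntheticPatient, generate_cohort
from .preprocess import (
    PVCConfig,
    compute_suv,
    discretize_fbn,
    mask_intersection,
    matv,
    van_cittert,
)

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "TEXT_PAIRS",
    "FIGURE_PAIRS",
    "ZONE_PAIRS",
    "extract_features_voi",
    "extract_cohort",
    "run_pairwise_experiment",
    "run_sweep_experiment",
    "run_matv_correlation",
]

#: the nine GLCM/GLRLM method pairs of the default (text) comparison design
TEXT_PAIRS: tuple[tuple[str, str], ...] = (
    ("2D_averaged", "2D_s_merged"),
    ("2.5D_d_merged", "2.5D_merged"),
    ("3D_averaged", "3D_merged"),
    ("2D_averaged", "2.5D_d_merged"),
    ("2D_averaged", "3D_averaged"),
    ("2.5D_d_merged", "3D_averaged"),
    ("2D_s_merged", "2.5D_merged"),
    ("2D_s_merged", "3D_merged"),
    ("2.5D_merged", "3D_merged"),
)

#: figure-caption variant: one cross-dimension pair swapped
FIGURE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    ("2D_averaged", "2.5D_merged") if p == ("2D_averaged", "3D_averaged") else p
    for p in TEXT_PAIRS
)

ZONE_PAIRS: tuple[tuple[str, str], ...] = (("2D", "2.5D"), ("2D", "3D"), ("2.5D", "3D"))


@dataclass
class ExperimentConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    fbn_levels: tuple[int, ...] = (8, 16, 32, 64, 128)
    pvc_fwhm_levels: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    default_fbn: int = 128
    pvc_alpha: float = 1.0
    pvc_iterations: int = 10
    pair_variant: str = "text"  # or "figure"
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 2 for d in self.fbn_levels):
            raise ValueError("FBN levels must be >= 2")
        if self.pair_variant not in ("text", "figure"):
            raise ValueError("pair_variant must be 'text' or 'figure'")

    @property
    def glcm_glrlm_pairs(self) -> tuple[tuple[str, str], ...]:
        return TEXT_PAIRS if self.pair_variant == "text" else FIGURE_PAIRS

    def pairs_for_family(self, family: str) -> tuple[tuple[str, str], ...]:
        return self.glcm_glrlm_pairs if family in ("GLCM", "GLRLM") else ZONE_PAIRS


def extract_features_voi(voi) -> pd.DataFrame:
    """All 95 features under every legal aggregation method for one VOI.

    Returns tidy rows (family, feature, method, value); unit matrices are
    shared across methods of the same dimensionality.
    """
    rows = []
    for family in texmat.FAMILIES:
        fn = feat.feature_fn_for_family(family)
        methods = texmat.methods_for_family(family)
        units_2d = texmat.build_units(voi, family, methods[0])
        units_3d = texmat.build_units(voi, family, methods[-1])
        for method in methods:
            units = units_3d if method.startswith("3D") else units_2d
            vals = texmat.aggregate(voi, family, method, fn, units=units)
            rows.extend(
                dict(family=family, feature=k, method=method, value=v)
                for k, v in vals.items()
            )
    return pd.DataFrame(rows)


def _crop_to_roi(suv: ImageVolume, mask: ROIMask, pad: int) -> tuple[ImageVolume, ROIMask]:
    idx = np.nonzero(mask.values)
    box = tuple(
        slice(max(0, int(i.min()) - pad), min(n, int(i.max()) + 1 + pad))
        for i, n in zip(idx, mask.shape)
    )
    return (
        ImageVolume(suv.values[box], suv.spacing_mm),
        ROIMask(mask.values[box], mask.spacing_mm),
    )


def _patient_suv_and_mask(patient: SyntheticPatient) -> tuple[ImageVolume, ROIMask]:
    mask = mask_intersection(patient.mask_observer1, patient.mask_observer2)
    suv = compute_suv(patient.activity_volume, patient.injected_dose_bq, patient.body_weight_g)
    # crop with enough margin for the widest PVC kernel (FWHM 5 mm, +-3 sigma)
    return _crop_to_roi(suv, mask, pad=8)


def extract_cohort(
    cohort: list[SyntheticPatient],
    cfg: ExperimentConfig,
    configurations: list[tuple[int, float | None]] | None = None,
) -> pd.DataFrame:
    """Tidy feature table over (patient, configuration, family, method, feature).

    ``configurations`` is a list of (fbn, pvc_fwhm-or-None); the default runs
    the FBN sweep on uncorrected images plus the PVC sweep at the default FBN.
    Patients failing extraction are excluded with a logged reason; the run
    aborts if fewer than half the cohort is usable.
    """
    if configurations is None:
        configurations = [(d, None) for d in cfg.fbn_levels]
        configurations += [(cfg.default_fbn, f) for f in cfg.pvc_fwhm_levels]

    frames = []
    failed = 0
    for patient in cohort:
        try:
            suv, mask = _patient_suv_and_mask(patient)
            by_fwhm: dict[float | None, ImageVolume] = {None: suv}
            for fbn, fwhm in configurations:
                if fwhm not in by_fwhm:
                    pvc_cfg = PVCConfig(
                        psf_fwhm_mm=fwhm, alpha=cfg.pvc_alpha, n_iterations=cfg.pvc_iterations
                    )
                    by_fwhm[fwhm] = van_cittert(suv, pvc_cfg)
                voi = discretize_fbn(by_fwhm[fwhm], mask, fbn)
                df = extract_features_voi(voi)
                df["patient_id"] = patient.patient_id
                df["fbn"] = fbn
                df["pvc_fwhm"] = 0.0 if fwhm is None else float(fwhm)
                frames.append(df)
        except Exception:  # noqa: BLE001 - per-patient exclusion is the contract
            failed += 1
            log.exception("patient %s failed extraction; excluded", patient.patient_id)
    if failed > len(cohort) // 2:
        raise RuntimeError(f"{failed}/{len(cohort)} patients failed extraction")
    return pd.concat(frames, ignore_index=True)


def cohort_matv(cohort: list[SyntheticPatient]) -> pd.Series:
    """MATV (mL) of each patient's intersection VOI."""
    vals = {}
    for p in cohort:
        m = mask_intersection(p.mask_observer1, p.mask_observer2)
        vals[p.patient_id] = matv(m)
    return pd.Series(vals, name="matv_ml")


def run_pairwise_experiment(
    cfg: ExperimentConfig,
    features: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Pairwise ICC per family at the default FBN on uncorrected images."""
    from .robustness import pairwise_icc_table

    base = features[(features["fbn"] == cfg.default_fbn) & (features["pvc_fwhm"] == 0.0)]
    if base.empty:
        raise ValueError("feature table lacks the default (FBN, no-PVC) configuration")
    out = {}
    for family in texmat.FAMILIES:
        sub = base[base["family"] == family]
        out[family] = pairwise_icc_table(sub, list(cfg.pairs_for_family(family)))
    return out


def run_sweep_experiment(
    cfg: ExperimentConfig,
    features: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Overall ICC per feature per configuration and its category distributions.

    Configuration axis (a): FBN sweep on uncorrected images; (b): PVC FWHM
    sweep at the default FBN.  Returns the overall-ICC table plus percent-per-
    category tables, overall and per family.
    """
    from .robustness import category_distribution, overall_icc_table

    blocks = []
    sweeps = [("fbn", fbn, 0.0) for fbn in cfg.fbn_levels]
    sweeps += [("pvc", cfg.default_fbn, float(f)) for f in cfg.pvc_fwhm_levels]
    for sweep, fbn, fwhm in sweeps:
        sub = features[(features["fbn"] == fbn) & (features["pvc_fwhm"] == fwhm)]
        if sub.empty:
            continue
        for family in texmat.FAMILIES:
            tab = overall_icc_table(
                sub[sub["family"] == family], list(texmat.methods_for_family(family))
            )
            tab["sweep"] = sweep
            tab["configuration"] = f"FBN{fbn}" if sweep == "fbn" else f"PVC{fwhm:g}"
            blocks.append(tab)
    overall = pd.concat(blocks, ignore_index=True)
    return {
        "overall_icc": overall,
        "categories_all": category_distribution(overall, ["sweep", "configuration"]),
        "categories_by_family": category_distribution(
            overall, ["sweep", "configuration", "family"]
        ),
    }


def select_excellent_features(pairwise: dict[str, pd.DataFrame]) -> list[tuple[str, str]]:
    """(family, feature) pairs with ICC >= 0.9 across every configured pair."""
    out = []
    for family, tab in pairwise.items():
        if tab.empty:
            continue
        ok = tab.groupby("feature")["icc"].min() >= 0.9
        out.extend((family, f) for f in ok[ok].index)
    return out


def run_matv_correlation(
    cfg: ExperimentConfig,
    features: pd.DataFrame,
    matv_ml: pd.Series,
    feature_subset: list[tuple[str, str]],
) -> pd.DataFrame:
    """|Spearman| between each selected feature and MATV per configuration.

    The selected features are typically those with excellent pairwise
    robustness; the subset must be explicit and nonempty.
    """
    from .robustness import spearman_abs

    if not feature_subset:
        raise ValueError("empty feature subset for the MATV correlation study")
    rows = []
    for (fbn, fwhm), sub in features.groupby(["fbn", "pvc_fwhm"]):
        for family, feature in feature_subset:
            for method in texmat.methods_for_family(family):
                s = sub[
                    (sub["family"] == family)
                    & (sub["feature"] == feature)
                    & (sub["method"] == method)
                ].set_index("patient_id")["value"].dropna()
                joined = pd.concat([s, matv_ml], axis=1, join="inner").dropna()
                if len(joined) < 3 or joined.iloc[:, 0].nunique() < 2:
                    continue
                r = spearman_abs(
                    joined.iloc[:, 0].to_numpy(), joined["matv_ml"].to_numpy(), feature
                )
                rows.append(
                    dict(
                        family=family,
                        feature=feature,
                        method=method,
                        fbn=fbn,
                        pvc_fwhm=fwhm,
                        rs_abs=r.rs_abs,
                        sign=r.sign,
                        n=r.n,
                    )
                )
    return pd.DataFrame(rows)


def run_study(cfg: ExperimentConfig) -> dict[str, object]:
    """The full study on a phantom cohort: extraction, pairwise ICC, sweeps,
    and the MATV correlation of the excellent-robustness features."""
    cohort = generate_cohort(cfg.phantom)
    features = extract_cohort(cohort, cfg)
    pairwise = run_pairwise_experiment(cfg, features)
    sweep = run_sweep_experiment(cfg, features)
    excellent = select_excellent_features(pairwise)
    matv_ml = cohort_matv(cohort)
    corr = (
        run_matv_correlation(cfg, features, matv_ml, excellent)
        if excellent
        else pd.DataFrame()
    )
    results = {
        "cohort": cohort,
        "features": features,
        "pairwise": pairwise,
        "sweep": sweep,
        "excellent": excellent,
        "matv": matv_ml,
        "matv_correlation": corr,
    }
    if cfg.out_dir is not None:
        _write_tables(cfg, results)
    return results


def _write_tables(cfg: ExperimentConfig, results: dict[str, object]) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["features"].to_csv(out / "features.tsv", sep="\t", index=False)
    for family, tab in results["pairwise"].items():
        tab.to_csv(out / f"pairwise_icc_{family.lower()}.tsv", sep="\t", index=False)
    for key in ("overall_icc", "categories_all", "categories_by_family"):
        results["sweep"][key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    results["matv"].to_csv(out / "matv.tsv", sep="\t")
    if len(results["matv_correlation"]):
        results["matv_correlation"].to_csv(out / "matv_correlation.tsv", sep="\t", index=False)
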