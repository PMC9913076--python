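"""The 95 texture features over the six matrix families.

Counts per family: GLCM 25, GLRLM 16, GLSZM 16, GLDZM 16, NGTDM 5, NGLDM 17.
Formulas follow the image-biomarker standardisation (IBSI) reference
definitions: entropies in bits (log base 2, with 0*log 0 = 0), grey levels
taken at their actual bin values, and sums restricted to grey levels present
in the matrix.  Degenerate inputs get the standard special-case values
(e.g. GLCM correlation = 1 when the VOI holds a single grey level, NGTDM
coarseness capped when every neighbourhood difference vanishes).

An empty-flagged matrix yields NaN for every feature of its family — the
degenerate marker that downstream ICC code drops with logging.
"""

from __future__ import annotations

import numpy as np

from .texmat import TextureMatrix

__all__ = [
    "FEATURE_REGISTRY",
    "registry_counts",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngtdm_features",
    "ngldm_features",
    "feature_fn_for_family",
]

COARSENESS_CAP = 1.0e6

GLCM_NAMES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)

GLRLM_NAMES = (
    "short_runs_emphasis",
    "long_runs_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
)

GLSZM_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalized",
    "zone_percentage",
    "grey_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

GLDZM_NAMES = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized",
    "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalized",
    "zone_percentage",
    "grey_level_variance",
    "zone_distance_variance",
    "zone_distance_entropy",
)

NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

NGLDM_NAMES = (
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_grey_level_count_emphasis",
    "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalized",
    "dependence_count_percentage",
    "grey_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
    "dependence_count_energy",
)

#: ordered (family, feature_name) pairs — 25/16/16/16/5/17 = 95 entries
FEATURE_REGISTRY: tuple[tuple[str, str], ...] = tuple(
    (fam, name)
    for fam, names in (
        ("GLCM", GLCM_NAMES),
        ("GLRLM", GLRLM_NAMES),
        ("GLSZM", GLSZM_NAMES),
        ("GLDZM", GLDZM_NAMES),
        ("NGTDM", NGTDM_NAMES),
        ("NGLDM", NGLDM_NAMES),
    )
    for name in names
)


def registry_counts() -> dict[str, int]:
    out: dict[str, int] = {}
    for fam, _ in FEATURE_REGISTRY:
        out[fam] = out.get(fam, 0) + 1
    return out


def _nan_vector(names: tuple[str, ...]) -> dict[str, float]:
    return {n: float("nan") for n in names}


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    """The 25 co-occurrence features from a symmetric count or probability matrix."""
    if tm.empty or tm.counts.sum() <= 0:
        return _nan_vector(GLCM_NAMES)
    P = tm.counts / tm.counts.sum()
    D = P.shape[0]
    levels = np.arange(1, D + 1, dtype=np.float64)
    ii, jj = np.nonzero(P)
    w = P[ii, jj]
    gi = levels[ii]
    gj = levels[jj]

    p_i = P.sum(axis=1)
    present = p_i > 0
    n_g = int(present.sum())
    mu = float(np.sum(levels * p_i))
    var = float(np.sum((levels - mu) ** 2 * p_i))

    adiff = np.abs(gi - gj)
    ssum = gi + gj
    # difference / sum marginal distributions
    p_diff = np.bincount(adiff.astype(int), weights=w, minlength=D)
    p_sum = np.bincount(ssum.astype(int), weights=w, minlength=2 * D + 1)
    kd = np.arange(p_diff.size, dtype=np.float64)
    ks = np.arange(p_sum.size, dtype=np.float64)
    mu_d = float(np.sum(kd * p_diff))
    mu_s = float(np.sum(ks * p_sum))

    h_xy = float(-np.sum(_xlog2(w)))
    h_x = float(-np.sum(_xlog2(p_i[present])))
    pipj = p_i[ii] * p_i[jj]
    h_xy1 = float(-np.sum(w * np.log2(pipj)))
    pp = np.outer(p_i[present], p_i[present])
    h_xy2 = float(-np.sum(_xlog2(pp)))

    if var > 0:
        corr = float((np.sum(w * gi * gj) - mu * mu) / var)
    else:
        corr = 1.0  # single grey level: perfectly correlated by convention
    ic1 = (h_xy - h_xy1) / h_x if h_x > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (h_xy2 - h_xy)))))

    off = adiff > 0
    return {
        "joint_maximum": float(w.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": h_xy,
        "difference_average": mu_d,
        "difference_variance": float(np.sum((kd - mu_d) ** 2 * p_diff)),
        "difference_entropy": float(-np.sum(_xlog2(p_diff))),
        "sum_average": mu_s,
        "sum_variance": float(np.sum((ks - mu_s) ** 2 * p_sum)),
        "sum_entropy": float(-np.sum(_xlog2(p_sum))),
        "angular_second_moment": float(np.sum(w**2)),
        "contrast": float(np.sum(w * (gi - gj) ** 2)),
        "dissimilarity": float(np.sum(w * adiff)),
        "inverse_difference": float(np.sum(w / (1.0 + adiff))),
        "inverse_difference_normalized": float(np.sum(w / (1.0 + adiff / n_g))),
        "inverse_difference_moment": float(np.sum(w / (1.0 + adiff**2))),
        "inverse_difference_moment_normalized": float(np.sum(w / (1.0 + adiff**2 / n_g**2))),
        "inverse_variance": float(np.sum(w[off] / adiff[off] ** 2)),
        "correlation": corr,
        "autocorrelation": float(np.sum(w * gi * gj)),
        "cluster_tendency": float(np.sum(w * (ssum - 2 * mu) ** 2)),
        "cluster_shade": float(np.sum(w * (ssum - 2 * mu) ** 3)),
        "cluster_prominence": float(np.sum(w * (ssum - 2 * mu) ** 4)),
        "information_correlation_1": float(ic1),
        "information_correlation_2": ic2,
    }


def _rlm_style(tm: TextureMatrix, prefix: dict[str, str]) -> dict[str, float]:
    """Shared algebra of the run/zone/dependence families.

    ``prefix`` maps the generic keys (se, le, ...) onto family names.  The
    column axis value for column index c is c+1 (run length, zone size, zone
    distance, or dependence count k+1).
    """
    S = tm.counts
    n_s = S.sum()
    D, nc = S.shape
    i = np.arange(1, D + 1, dtype=np.float64)
    j = np.arange(1, nc + 1, dtype=np.float64)
    r_i = S.sum(axis=1)
    c_j = S.sum(axis=0)
    P = S / n_s
    mu_i = float(np.sum(i * P.sum(axis=1)))
    mu_j = float(np.sum(j * P.sum(axis=0)))
    inv_i2 = 1.0 / i**2
    inv_j2 = 1.0 / j**2
    out = {
        prefix["se"]: float(np.sum(c_j * inv_j2) / n_s),
        prefix["le"]: float(np.sum(c_j * j**2) / n_s),
        prefix["lgle"]: float(np.sum(r_i * inv_i2) / n_s),
        prefix["hgle"]: float(np.sum(r_i * i**2) / n_s),
        prefix["slgle"]: float(np.sum(S * np.outer(inv_i2, inv_j2)) / n_s),
        prefix["shgle"]: float(np.sum(S * np.outer(i**2, inv_j2)) / n_s),
        prefix["llgle"]: float(np.sum(S * np.outer(inv_i2, j**2)) / n_s),
        prefix["lhgle"]: float(np.sum(S * np.outer(i**2, j**2)) / n_s),
        prefix["gln"]: float(np.sum(r_i**2) / n_s),
        prefix["glnn"]: float(np.sum(r_i**2) / n_s**2),
        prefix["nun"]: float(np.sum(c_j**2) / n_s),
        prefix["nunn"]: float(np.sum(c_j**2) / n_s**2),
        prefix["pct"]: float(n_s / tm.n_voxels),
        prefix["glv"]: float(np.sum((i[:, None] - mu_i) ** 2 * P)),
        prefix["nv"]: float(np.sum((j[None, :] - mu_j) ** 2 * P)),
        prefix["ent"]: float(-np.sum(_xlog2(P.ravel()))),
    }
    if "energy" in prefix:
        out[prefix["energy"]] = float(np.sum(P**2))
    return out


_GLRLM_KEYS = dict(
    se="short_runs_emphasis",
    le="long_runs_emphasis",
    lgle="low_grey_level_run_emphasis",
    hgle="high_grey_level_run_emphasis",
    slgle="short_run_low_grey_level_emphasis",
    shgle="short_run_high_grey_level_emphasis",
    llgle="long_run_low_grey_level_emphasis",
    lhgle="long_run_high_grey_level_emphasis",
    gln="grey_level_non_uniformity",
    glnn="grey_level_non_uniformity_normalized",
    nun="run_length_non_uniformity",
    nunn="run_length_non_uniformity_normalized",
    pct="run_percentage",
    glv="grey_level_variance",
    nv="run_length_variance",
    ent="run_entropy",
)

_GLSZM_KEYS = dict(
    se="small_zone_emphasis",
    le="large_zone_emphasis",
    lgle="low_grey_level_zone_emphasis",
    hgle="high_grey_level_zone_emphasis",
    slgle="small_zone_low_grey_level_emphasis",
    shgle="small_zone_high_grey_level_emphasis",
    llgle="large_zone_low_grey_level_emphasis",
    lhgle="large_zone_high_grey_level_emphasis",
    gln="grey_level_non_uniformity",
    glnn="grey_level_non_uniformity_normalized",
    nun="zone_size_non_uniformity",
    nunn="zone_size_non_uniformity_normalized",
    pct="zone_percentage",
    glv="grey_level_variance",
    nv="zone_size_variance",
    ent="zone_size_entropy",
)

_GLDZM_KEYS = dict(
    se="small_distance_emphasis",
    le="large_distance_emphasis",
    lgle="low_grey_level_zone_emphasis",
    hgle="high_grey_level_zone_emphasis",
    slgle="small_distance_low_grey_level_emphasis",
    shgle="small_distance_high_grey_level_emphasis",
    llgle="large_distance_low_grey_level_emphasis",
    lhgle="large_distance_high_grey_level_emphasis",
    gln="grey_level_non_uniformity",
    glnn="grey_level_non_uniformity_normalized",
    nun="zone_distance_non_uniformity",
    nunn="zone_distance_non_uniformity_normalized",
    pct="zone_percentage",
    glv="grey_level_variance",
    nv="zone_distance_variance",
    ent="zone_distance_entropy",
)

_NGLDM_KEYS = dict(
    se="low_dependence_emphasis",
    le="high_dependence_emphasis",
    lgle="low_grey_level_count_emphasis",
    hgle="high_grey_level_count_emphasis",
    slgle="low_dependence_low_grey_level_emphasis",
    shgle="low_dependence_high_grey_level_emphasis",
    llgle="high_dependence_low_grey_level_emphasis",
    lhgle="high_dependence_high_grey_level_emphasis",
    gln="grey_level_non_uniformity",
    glnn="grey_level_non_uniformity_normalized",
    nun="dependence_count_non_uniformity",
    nunn="dependence_count_non_uniformity_normalized",
    pct="dependence_count_percentage",
    glv="grey_level_variance",
    nv="dependence_count_variance",
    ent="dependence_count_entropy",
    energy="dependence_count_energy",
)


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    """16 run-length features; run percentage uses the unit's in-ROI voxel count."""
    if tm.empty or tm.counts.sum() <= 0:
        return _nan_vector(GLRLM_NAMES)
    return _rlm_style(tm, _GLRLM_KEYS)


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    """16 size-zone features (zone size as the second axis)."""
    if tm.empty or tm.counts.sum() <= 0:
        return _nan_vector(GLSZM_NAMES)
    return _rlm_style(tm, _GLSZM_KEYS)


def gldzm_features(tm: TextureMatrix) -> dict[str, float]:
    """16 distance-zone features (zone distance as the second axis)."""
    if tm.empty or tm.counts.sum() <= 0:
        return _nan_vector(GLDZM_NAMES)
    return _rlm_style(tm, _GLDZM_KEYS)


def ngldm_features(tm: TextureMatrix) -> dict[str, float]:
    """17 dependence-count features (the zone algebra plus energy)."""
    if tm.empty or tm.counts.sum() <= 0:
        return _nan_vector(NGLDM_NAMES)
    return _rlm_style(tm, _NGLDM_KEYS)


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength.

    ``tm.counts`` holds per-grey columns (n_i, s_i).  Special cases: a single
    present grey level gives contrast = busyness = 0; a vanishing sum p*s
    caps coarseness at 1e6; vanishing total s gives strength = 0.
    """
    if tm.empty or tm.counts[:, 0].sum() <= 0:
        return _nan_vector(NGTDM_NAMES)
    n = tm.counts[:, 0]
    s = tm.counts[:, 1]
    N = n.sum()
    p = n / N
    pres = p > 0
    i = np.arange(1, len(n) + 1, dtype=np.float64)
    ip, pp, sp = i[pres], p[pres], s[pres]
    n_gp = int(pres.sum())

    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if n_gp > 1:
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float(
            np.sum(pp[:, None] * pp[None, :] * dij2) / (n_gp * (n_gp - 1)) * (s.sum() / N)
        )
        denom = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0

    adiff = np.abs(ip[:, None] - ip[None, :])
    complexity = float(
        np.sum(adiff * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / (pp[:, None] + pp[None, :]))
        / N
    )
    s_tot = float(s.sum())
    if s_tot > 0:
        strength = float(np.sum((pp[:, None] + pp[None, :]) * (ip[:, None] - ip[None, :]) ** 2) / s_tot)
    else:
        strength = 0.0
    return {
        "coarseness": float(coarseness),
        "contrast": contrast,
        "busyness": float(busyness),
        "complexity": complexity,
        "strength": strength,
    }


_FAMILY_FNS = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "GLDZM": gldzm_features,
    "NGTDM": ngtdm_features,
    "NGLDM": ngldm_features,
}


def feature_fn_for_family(family: str):
    return _FAMILY_FNS[family]
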