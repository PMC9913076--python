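"""Feature-robustness statistics: one-way ICC, robustness categories,
category distributions, and absolute Spearman correlation with MATV.

The ICC used throughout is (BMS - WMS) / (BMS + WMS) with BMS and WMS the
between- and within-subject mean squares of a one-way random-effects ANOVA
(at k = 2 replicates this equals the classical ICC(1,1)).  Values below zero
are reported as computed but always categorize as "poor".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "icc",
    "categorize",
    "CATEGORIES",
    "pairwise_icc_table",
    "overall_icc_table",
    "category_distribution",
    "spearman_abs",
]

CATEGORIES = ("poor", "moderate", "good", "excellent")


def icc(values: np.ndarray, rank_transform: bool = False) -> float:
    """One-way random-effects ICC of a subjects x replicates table.

    BMS has df = n - 1, WMS has df = n (k - 1); returns
    (BMS - WMS) / (BMS + WMS).  If every cell is identical (BMS + WMS = 0)
    the value is defined as 1 (perfect agreement, logged as degenerate).
    ``rank_transform`` replaces values by their global ranks first
    (sensitivity variant).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2D table with >=2 subjects and >=2 replicates")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC table contains missing values; drop those rows first")
    if rank_transform:
        x = stats.rankdata(x).reshape(x.shape)
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    bms = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    wms = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    denom = bms + wms
    if denom == 0:
        log.debug("degenerate ICC: zero total variance; returning 1")
        return 1.0
    return float((bms - wms) / denom)


def categorize(value: float) -> str:
    """Robustness category at thresholds 0.5 / 0.75 / 0.9 (left-closed)."""
    if value >= 0.9:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def _icc_rows(
    features: pd.DataFrame,
    replicate_sets: dict[str, list[str]],
    rank_transform: bool,
) -> pd.DataFrame:
    """Shared driver for pairwise/overall tables.

    ``features`` is tidy with columns (patient_id, family, feature, method,
    value); ``replicate_sets`` maps a comparison label to the list of methods
    forming its replicates.
    """
    rows = []
    for (family, feature), grp in features.groupby(["family", "feature"], sort=False):
        wide = grp.pivot_table(index="patient_id", columns="method", values="value")
        for label, methods in replicate_sets.items():
            if any(m not in wide.columns for m in methods):
                continue
            block = wide[list(methods)].dropna()
            dropped = len(wide) - len(block)
            if dropped:
                log.info(
                    "ICC %s/%s %s: dropped %d subject(s) with degenerate values",
                    family, feature, label, dropped,
                )
            if len(block) < 2:
                log.warning("ICC %s/%s %s: <2 usable subjects, skipped", family, feature, label)
                continue
            val = icc(block.to_numpy(), rank_transform=rank_transform)
            rows.append(
                dict(
                    family=family,
                    feature=feature,
                    comparison=label,
                    icc=val,
                    category=categorize(val),
                    n_subjects=len(block),
                )
            )
    return pd.DataFrame(rows)


def pairwise_icc_table(
    features: pd.DataFrame,
    pairs: list[tuple[str, str]],
    rank_transform: bool = False,
) -> pd.DataFrame:
    """One ICC per (feature, method pair), k = 2 replicates."""
    sets = {f"{a}-{b}": [a, b] for a, b in pairs}
    return _icc_rows(features, sets, rank_transform)


def overall_icc_table(
    features: pd.DataFrame,
    methods: list[str],
    rank_transform: bool = False,
) -> pd.DataFrame:
    """One ICC per feature across all given aggregation methods (k = len(methods))."""
    return _icc_rows(features, {"overall": list(methods)}, rank_transform)


def category_distribution(results: pd.DataFrame, group_by: list[str] | None = None) -> pd.DataFrame:
    """Percent of features per robustness category, optionally per group.

    Returns one row per group with columns poor/moderate/good/excellent
    summing to 100.
    """
    if results.empty:
        raise ValueError("no ICC results to summarize")

    def pct(df: pd.DataFrame) -> pd.Series:
        c = df["category"].value_counts()
        total = len(df)
        return pd.Series({cat: 100.0 * c.get(cat, 0) / total for cat in CATEGORIES})

    if not group_by:
        return pct(results).to_frame().T
    return results.groupby(group_by, sort=False).apply(pct, include_groups=False).reset_index()


@dataclass
class CorrelationResult:
    feature: str
    rs_abs: float
    sign: str
    n: int


def spearman_abs(feature_values: np.ndarray, matv_values: np.ndarray, name: str = "") -> CorrelationResult:
    """Absolute Spearman rank correlation with the recovered sign.

    Ties get average ranks (scipy).  Zero variance in either vector makes the
    correlation undefined and raises.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(matv_values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 subjects for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    rs = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(name, abs(rs), "+" if rs >= 0 else "-", x.size)
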