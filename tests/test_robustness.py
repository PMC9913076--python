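"""ICC against hand one-way ANOVA, categorization thresholds, table drivers,
category distributions, and the Spearman correlation utilities."""

import numpy as np
import pandas as pd
import pytest

from texagg.robustness import (
    CATEGORIES,
    categorize,
    category_distribution,
    icc,
    overall_icc_table,
    pairwise_icc_table,
    spearman_abs,
)

from _oracles import bf_icc, bf_spearman


class TestICC:
    def test_hand_anova_example(self):
        assert icc(np.array([[1, 2], [3, 4], [5, 6]])) == pytest.approx(7.5 / 8.5)

    def test_identical_replicates(self):
        assert icc(np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])) == 1.0

    def test_negative_icc_case(self):
        assert icc(np.array([[0.0, 1.0], [0.0, 1.0]])) == pytest.approx(-1.0)

    def test_all_identical_defined_as_one(self):
        assert icc(np.full((4, 3), 2.2)) == 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for k in (2, 3, 6):
            x = rng.normal(size=(9, k)) + rng.normal(size=(9, 1)) * 2
            assert icc(x) == pytest.approx(bf_icc(x), rel=1e-12)

    def test_matches_pingouin_icc1_at_k2(self):
        """At k = 2 the (BMS-WMS)/(BMS+WMS) form equals the classical ICC(1,1)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1)) * 1.5
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "value": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="value")
        row = ref[ref["Type"].isin(["ICC1", "ICC(1,1)"])]
        icc1 = float(row["ICC"].iloc[0])
        assert icc(x) == pytest.approx(icc1, rel=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(8, 3))
        assert icc(x + 100.0) == pytest.approx(icc(x), rel=1e-9)
        assert icc(x * 42.0) == pytest.approx(icc(x), rel=1e-9)

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            assert icc(rng.normal(size=(6, 4))) <= 1.0

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.95, "excellent"), (0.9, "excellent"), (0.899, "good"), (0.75, "good"),
            (0.749, "moderate"), (0.5, "moderate"), (0.49, "poor"), (-0.2, "poor"),
        ],
    )
    def test_thresholds_left_closed(self, value, expected):
        assert categorize(value) == expected

    def test_categories_reproducible_from_stored_icc(self):
        rng = np.random.default_rng(14)
        df = _toy_features(rng, n=6)
        tab = pairwise_icc_table(df, [("A", "B")])
        for _, row in tab.iterrows():
            assert categorize(row["icc"]) == row["category"]


def _toy_features(rng, n=6, methods=("A", "B"), features=("f1", "f2"), offset=0.0):
    rows = []
    for pid in range(n):
        base = rng.normal(size=len(features)) * 3
        for im, m in enumerate(methods):
            for f, b in zip(features, base):
                rows.append(
                    dict(
                        patient_id=f"P{pid}",
                        family="GLCM",
                        feature=f,
                        method=m,
                        value=b + rng.normal() * 0.1 + offset * im,
                    )
                )
    return pd.DataFrame(rows)


class TestTables:
    def test_identical_columns_give_one(self):
        rng = np.random.default_rng(15)
        df = _toy_features(rng)
        dup = df[df["method"] == "A"].assign(method="B")
        tab = pairwise_icc_table(pd.concat([df[df["method"] == "A"], dup]), [("A", "B")])
        assert (tab["icc"] == 1.0).all()
        assert (tab["category"] == "excellent").all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(16)
        df = _toy_features(rng)
        tab1 = pairwise_icc_table(df, [("A", "B")]).set_index("feature")["icc"]
        shuffled = df.sample(frac=1.0, random_state=1)
        tab2 = pairwise_icc_table(shuffled, [("A", "B")]).set_index("feature")["icc"]
        pd.testing.assert_series_equal(tab1.sort_index(), tab2.sort_index())

    def test_constant_offset_matches_oracle(self):
        rng = np.random.default_rng(17)
        df = _toy_features(rng, offset=1.5)
        tab = pairwise_icc_table(df, [("A", "B")])
        for feature in ("f1", "f2"):
            wide = df[df["feature"] == feature].pivot(
                index="patient_id", columns="method", values="value"
            )
            expect = bf_icc(wide[["A", "B"]].to_numpy())
            got = float(tab.loc[tab["feature"] == feature, "icc"].iloc[0])
            assert got == pytest.approx(expect, rel=1e-12)
            assert got < 1.0

    def test_overall_k2_reduces_to_pairwise(self):
        rng = np.random.default_rng(18)
        df = _toy_features(rng)
        pw = pairwise_icc_table(df, [("A", "B")]).set_index("feature")["icc"]
        ov = overall_icc_table(df, ["A", "B"]).set_index("feature")["icc"]
        pd.testing.assert_series_equal(pw.sort_index(), ov.sort_index(), check_names=False)

    def test_overall_matches_oracle_4x3(self):
        rng = np.random.default_rng(19)
        df = _toy_features(rng, n=4, methods=("A", "B", "C"), features=("f1",))
        wide = df.pivot(index="patient_id", columns="method", values="value")
        got = overall_icc_table(df, ["A", "B", "C"])["icc"].iloc[0]
        assert got == pytest.approx(bf_icc(wide[["A", "B", "C"]].to_numpy()), rel=1e-12)

    def test_degenerate_rows_dropped(self):
        rng = np.random.default_rng(20)
        df = _toy_features(rng, n=5)
        df.loc[(df["patient_id"] == "P0") & (df["method"] == "A"), "value"] = np.nan
        tab = pairwise_icc_table(df, [("A", "B")])
        assert (tab["n_subjects"] == 4).all()


class TestCategoryDistribution:
    def test_all_excellent(self):
        df = pd.DataFrame({"category": ["excellent"] * 5})
        out = category_distribution(df)
        assert out["excellent"].iloc[0] == 100.0
        assert out[list(CATEGORIES)].iloc[0].sum() == 100.0

    def test_half_poor_half_good(self):
        df = pd.DataFrame({"category": ["poor", "poor", "good", "good"]})
        out = category_distribution(df)
        assert out["poor"].iloc[0] == 50.0 and out["good"].iloc[0] == 50.0

    def test_groups_sum_to_100(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(
            {
                "category": rng.choice(CATEGORIES, size=40),
                "configuration": rng.choice(["FBN8", "FBN128"], size=40),
            }
        )
        out = category_distribution(df, ["configuration"])
        np.testing.assert_allclose(out[list(CATEGORIES)].sum(axis=1), 100.0)


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        up = spearman_abs(x, x**3)
        down = spearman_abs(x, -np.exp(x))
        assert up.rs_abs == 1.0 and up.sign == "+"
        assert down.rs_abs == 1.0 and down.sign == "-"

    def test_hand_rank_example(self):
        r = spearman_abs(np.array([1, 2, 3, 4.0]), np.array([10, 30, 20, 40.0]))
        assert r.rs_abs == pytest.approx(0.8)
        assert r.rs_abs == pytest.approx(abs(bf_spearman([1, 2, 3, 4], [10, 30, 20, 40])))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(22)
        x = rng.random(15)
        y = rng.random(15)
        a = spearman_abs(x, y)
        b = spearman_abs(np.exp(3 * x), y**3 + 7)
        assert a.rs_abs == pytest.approx(b.rs_abs)

    def test_ties_average_ranks_match_oracle(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 2.0, 5.0, 4.0, 4.0])
        assert spearman_abs(x, y).rs_abs == pytest.approx(abs(bf_spearman(x, y)), rel=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            spearman_abs(np.ones(5), np.arange(5.0))
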