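import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microcensus import (
    OtuTable,
    TaxonomyMap,
    apply_family_filter,
    build_family_filter,
    welch_retain,
)
from microcensus.sewage import DEFAULT_EXCLUDED_FAMILIES, FamilyFilter


def _table(rows, samples, taxa, relative=False):
    return OtuTable(
        pd.DataFrame(rows, index=samples, columns=taxa, dtype=float),
        is_relative=relative,
    )


@pytest.fixture
def three_family_setup():
    table = _table([[60.0, 35.0, 5.0]], ["ref"], ["a", "b", "c"])
    taxonomy = TaxonomyMap({"a": "FamX", "b": "FamY", "c": "FamZ"})
    return table, taxonomy


class TestBuildFamilyFilter:
    def test_smallest_prefix_reaching_coverage(self, three_family_setup):
        table, taxonomy = three_family_setup
        f = build_family_filter(table, taxonomy, coverage=0.9, exclude=frozenset())
        assert f.retained == {"FamX", "FamY"}

    def test_excluded_family_removed_from_prefix(self):
        table = _table([[60.0, 35.0, 5.0]], ["ref"], ["a", "b", "c"])
        taxonomy = TaxonomyMap(
            {"a": "FamX", "b": "Enterobacteriaceae", "c": "FamZ"}
        )
        f = build_family_filter(table, taxonomy, coverage=0.9)
        assert "Enterobacteriaceae" not in f.retained
        assert "FamX" in f.retained

    def test_default_exclusions_are_the_two_water_families(self):
        assert DEFAULT_EXCLUDED_FAMILIES == {
            "Enterobacteriaceae",
            "Burkholderiaceae",
        }

    def test_empty_taxonomy_rejected(self, three_family_setup):
        table, _ = three_family_setup
        with pytest.raises(ValueError, match="empty"):
            build_family_filter(table, TaxonomyMap({}))

    def test_overlapping_retained_excluded_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FamilyFilter(
                retained={"FamX"}, coverage=0.99, excluded={"FamX"}
            )


class TestApplyFamilyFilter:
    def test_all_retained_is_identity_fraction(self, three_family_setup):
        table, taxonomy = three_family_setup
        f = FamilyFilter({"FamX", "FamY", "FamZ"}, coverage=0.99)
        filtered, fraction = apply_family_filter(table, taxonomy, f)
        assert fraction.tolist() == [1.0]
        np.testing.assert_allclose(filtered.values.sum(axis=1), 1.0)

    def test_hand_fraction_and_renormalization(self):
        table = _table([[50.0, 30.0, 20.0]], ["s"], ["a", "b", "w"])
        taxonomy = TaxonomyMap({"a": "FamX", "b": "FamX", "w": "Water"})
        f = FamilyFilter({"FamX"}, coverage=0.99)
        filtered, fraction = apply_family_filter(table, taxonomy, f)
        assert fraction.tolist() == [0.8]
        np.testing.assert_allclose(filtered.values, [[0.625, 0.375]])

    def test_idempotent(self, three_family_setup):
        table, taxonomy = three_family_setup
        f = FamilyFilter({"FamX", "FamY"}, coverage=0.99)
        once, _ = apply_family_filter(table, taxonomy, f)
        twice, frac = apply_family_filter(once, taxonomy, f)
        np.testing.assert_allclose(once.values, twice.values)
        assert frac.tolist() == [1.0]

    def test_weighted_mean_fraction_equals_total_ratio(self):
        table = _table(
            [[80.0, 20.0], [30.0, 70.0]], ["s1", "s2"], ["gut", "water"]
        )
        taxonomy = TaxonomyMap({"gut": "FamX", "water": "Water"})
        f = FamilyFilter({"FamX"}, coverage=0.99)
        _, fraction = apply_family_filter(table, taxonomy, f)
        totals = table.data.sum(axis=1)
        weighted = (fraction * totals).sum() / totals.sum()
        assert weighted == pytest.approx(110.0 / 200.0)


class TestWelchRetain:
    def test_identical_sides_retained_with_p_one(self):
        a = _table([[0.1], [0.2], [0.3]], ["s1", "s2", "s3"], ["otu"])
        b = _table([[0.1], [0.2], [0.3]], ["r1", "r2", "r3"], ["otu"])
        out = welch_retain(a, b)
        row = out.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert bool(row["retained"])

    def test_strong_shift_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.5, 0.05, size=20)
        a = _table(base[:, None], [f"s{i}" for i in range(20)], ["otu"])
        b = _table(
            (base + 10 * 0.05)[:, None], [f"r{i}" for i in range(20)], ["otu"]
        )
        out = welch_retain(a, b)
        assert out.iloc[0]["p"] < 1e-6
        assert not bool(out.iloc[0]["retained"])

    def test_matches_independent_t_distribution_cdf(self):
        rng = np.random.default_rng(1)
        a_vals = rng.normal(0.5, 0.05, 15)
        b_vals = rng.normal(0.52, 0.06, 12)
        a = _table(a_vals[:, None], [f"s{i}" for i in range(15)], ["otu"])
        b = _table(b_vals[:, None], [f"r{i}" for i in range(12)], ["otu"])
        row = welch_retain(a, b).iloc[0]
        # independent oracle: Welch t and Welch-Satterthwaite df by hand,
        # p from the t CDF
        va = a_vals.var(ddof=1) / 15
        vb = b_vals.var(ddof=1) / 12
        t = (a_vals.mean() - b_vals.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 14 + vb**2 / 11)
        p = 2 * stats.t.sf(abs(t), df)
        assert row["t"] == pytest.approx(t)
        assert row["df"] == pytest.approx(df)
        assert row["p"] == pytest.approx(p)

    def test_symmetric_in_table_order(self):
        rng = np.random.default_rng(2)
        a = _table(
            rng.normal(0.5, 0.1, (10, 2)), [f"s{i}" for i in range(10)], ["x", "y"]
        )
        b = _table(
            rng.normal(0.5, 0.1, (8, 2)), [f"r{i}" for i in range(8)], ["x", "y"]
        )
        ab = welch_retain(a, b).set_index("otu")["retained"]
        ba = welch_retain(b, a).set_index("otu")["retained"]
        pd.testing.assert_series_equal(ab, ba)

    def test_missing_otu_reported_not_retained(self):
        a = _table([[0.1, 0.4], [0.2, 0.5]], ["s1", "s2"], ["shared", "only_a"])
        b = _table([[0.1], [0.2]], ["r1", "r2"], ["shared"])
        out = welch_retain(a, b).set_index("otu")
        assert np.isnan(out.loc["only_a", "t"])
        assert not bool(out.loc["only_a", "retained"])

    def test_null_rejection_rate_calibrated(self):
        # both sides from one population: rejection at alpha = 0.05 should
        # sit near 0.05 (small Monte-Carlo run; the full calibration lives
        # in the acceptance suite)
        rng = np.random.default_rng(3)
        m = 800
        rejected = 0
        for _ in range(m):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0, 1, 25)
            if stats.ttest_ind(a, b, equal_var=False)[1] <= 0.05:
                rejected += 1
        assert rejected / m == pytest.approx(0.05, abs=0.025)
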