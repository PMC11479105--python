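import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcdblink.concordance import (AgreementReport, ConcordanceError, CrossTab,
                                  agreement_report, assign_quintiles,
                                  bland_altman, cohen_kappa_unweighted,
                                  compare_tables, difference_summary,
                                  kappa_band, normality_and_location_tests,
                                  pearson_with_test, quintile_crosstab,
                                  quintile_cutoffs, top_extreme)


def brute_force_kappa(qa, qb):
    """Independent oracle: contingency counts by explicit loops."""
    n = len(qa)
    counts = [[0] * 5 for _ in range(5)]
    for a, b in zip(qa, qb):
        counts[a][b] += 1
    po = sum(counts[i][i] for i in range(5)) / n
    pe = sum((sum(counts[i]) / n) * (sum(row[i] for row in counts) / n)
             for i in range(5))
    return (po - pe) / (1 - pe)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_with_test(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-9

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_with_test(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # cov = 1/3, sx = sy = sqrt(2/3) -> r = 0.5
        r, _ = pearson_with_test([1, 2, 3], [2, 1, 3])
        assert r == pytest.approx(0.5)

    def test_zero_variance_raises(self):
        with pytest.raises(ConcordanceError, match="variance"):
            pearson_with_test([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ConcordanceError):
            pearson_with_test([1, 2], [3, 4])


class TestQuintiles:
    def test_identity_all_diagonal(self):
        x = np.arange(100.0)
        ct = quintile_crosstab(x, x)
        assert ct.pct_agree == pytest.approx(100.0)
        assert np.allclose(np.diag(ct.matrix), 20.0)

    def test_cutoff_value_goes_to_lower_class(self):
        cutoffs = np.array([10.0, 20.0, 30.0, 40.0])
        assert assign_quintiles(np.array([10.0]), cutoffs)[0] == 0
        assert assign_quintiles(np.array([10.0001]), cutoffs)[0] == 1
        assert assign_quintiles(np.array([40.0]), cutoffs)[0] == 3
        assert assign_quintiles(np.array([41.0]), cutoffs)[0] == 4

    def test_printed_protein_diagonal(self, printed_crosstabs):
        ct = CrossTab.from_percentages(printed_crosstabs["protein"])
        assert round(ct.pct_agree) == 84

    def test_printed_carb_diagonal(self, printed_crosstabs):
        ct = CrossTab.from_percentages(printed_crosstabs["carb"])
        assert round(ct.pct_agree) == 68

    def test_cells_must_sum_to_100(self):
        bad = np.full((5, 5), 1.0)
        with pytest.raises(ConcordanceError, match="sum"):
            CrossTab.from_percentages(bad)

    def test_heavy_ties_warn(self):
        x = np.zeros(100)
        x[:5] = np.arange(1, 6)
        with pytest.warns(UserWarning, match="ties"):
            quintile_crosstab(x, x)


class TestKappa:
    def test_identity_is_one(self):
        m = np.zeros((5, 5))
        np.fill_diagonal(m, 20.0)
        assert cohen_kappa_unweighted(CrossTab.from_percentages(m)) == pytest.approx(1.0)

    def test_independent_uniform_is_zero(self):
        m = np.full((5, 5), 4.0)
        assert cohen_kappa_unweighted(CrossTab.from_percentages(m)) == pytest.approx(0.0)

    def test_printed_energy_value(self, printed_crosstabs):
        # po = 0.7821, pe ~ 0.2001 -> 0.7276
        ct = CrossTab.from_percentages(printed_crosstabs["energy"])
        k = cohen_kappa_unweighted(ct)
        assert k == pytest.approx(0.72758, abs=1e-4)
        assert round(k, 2) == 0.73

    def test_degenerate_pe_raises(self):
        m = np.zeros((5, 5))
        m[0, 0] = 100.0
        with pytest.raises(ConcordanceError):
            cohen_kappa_unweighted(CrossTab.from_percentages(m))

    def test_interpretation_bands(self):
        assert kappa_band(0.85) == "strong to very strong"
        assert kappa_band(0.65) == "moderate"
        assert kappa_band(0.45) == "weak"
        assert kappa_band(0.2) == "none to slight"

    @given(st.integers(0, 2**32 - 1), st.integers(20, 200))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_random_vectors(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.5, size=n)
        ct = quintile_crosstab(x, y)
        qa = assign_quintiles(x, quintile_cutoffs(x))
        qb = assign_quintiles(y, quintile_cutoffs(y))
        assert cohen_kappa_unweighted(ct) == pytest.approx(
            brute_force_kappa(qa, qb), rel=1e-9, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_kappa_bounded_by_agreement(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=80)
        y = x + rng.normal(scale=1.0, size=80)
        ct = quintile_crosstab(x, y)
        assert cohen_kappa_unweighted(ct) <= ct.pct_agree / 100.0 + 1e-12


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        bias, lo, hi, _ = bland_altman(x, x)
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_shift(self):
        x = np.arange(10.0)
        bias, lo, hi, _ = bland_altman(x, x - 5.0)
        assert bias == pytest.approx(5.0)
        assert lo == pytest.approx(5.0) and hi == pytest.approx(5.0)

    def test_closed_form_two_points(self):
        # diffs {0, 2}: bias 1, sample SD sqrt(2)
        bias, lo, hi, frame = bland_altman([1.0, 3.0], [1.0, 1.0])
        assert bias == pytest.approx(1.0)
        assert lo == pytest.approx(1.0 - 1.96 * np.sqrt(2.0))
        assert hi == pytest.approx(1.0 + 1.96 * np.sqrt(2.0))
        assert list(frame["diff"]) == [0.0, 2.0]

    def test_too_short_raises(self):
        with pytest.raises(ConcordanceError):
            bland_altman([1.0], [0.0])

    def test_gaussian_coverage_single_large_sample(self):
        rng = np.random.default_rng(7)
        d = rng.normal(2.0, 3.0, 20000)
        bias, lo, hi, _ = bland_altman(d, np.zeros_like(d))
        cover = np.mean((d >= lo) & (d <= hi))
        assert cover == pytest.approx(0.95, abs=0.01)


class TestDifferenceSummary:
    def test_all_zero(self):
        s = difference_summary(np.zeros(10))
        assert all(v == 0.0 for v in s.values())

    def test_symmetric_three(self):
        s = difference_summary([-1.0, 0.0, 1.0])
        assert s["median"] == 0.0 and s["mean"] == 0.0
        assert s["min"] == -1.0 and s["max"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ConcordanceError):
            difference_summary([])


class TestLocationTests:
    def test_exact_wilcoxon_small_sample(self):
        # 2^3 sign patterns; only all-positive reaches W+ = 6 -> p = 2/8
        _, wp = normality_and_location_tests([1.0, 2.0, 3.0])
        assert wp == pytest.approx(0.25)

    def test_all_zero_raises(self):
        with pytest.raises(ConcordanceError, match="zero"):
            normality_and_location_tests(np.zeros(10))

    def test_gaussian_ks_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        ks_p, _ = normality_and_location_tests(rng.normal(0, 1, 5000))
        assert 0.0 < ks_p <= 1.0


class TestTopExtreme:
    table = pd.DataFrame({"dish_id": ["a", "b", "c"],
                          "carb": [5.0, -3.0, 9.0],
                          "fat": [1.0, 2.0, 3.0]})

    def test_largest_absolute_first(self):
        top = top_extreme(self.table, "carb", k=2)
        assert top["dish_id"].tolist() == ["c", "a"]

    def test_k_equals_n_full_sort(self):
        top = top_extreme(self.table, "carb", k=3)
        assert top["dish_id"].tolist() == ["c", "a", "b"]

    def test_all_ties_ordered_by_dish_id(self):
        t = pd.DataFrame({"dish_id": ["z", "a", "m"], "carb": [1.0, 1.0, -1.0]})
        assert top_extreme(t, "carb", k=3)["dish_id"].tolist() == ["a", "m", "z"]

    def test_k_above_n_raises(self):
        with pytest.raises(ConcordanceError):
            top_extreme(self.table, "carb", k=4)

    def test_other_nutrient_percentiles_attached(self):
        top = top_extreme(self.table, "carb", k=1, other_nutrients=["fat"])
        assert top["pct_abs_fat"].iloc[0] == pytest.approx(100.0)


class TestCompareTables:
    @staticmethod
    def tables(delta=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3.0, 0.8, n)
        a = pd.DataFrame({"dish_id": [f"d{i}" for i in range(n)], "carb": base})
        b = a.copy()
        b["carb"] = base + delta
        return a, b

    def test_identical_tables_perfect_agreement(self):
        a, b = self.tables()
        rep = compare_tables(a, b, ["carb"], k=10)["carb"]
        assert rep.kappa == pytest.approx(1.0)
        assert rep.bias == pytest.approx(0.0)
        assert rep.pct_agree == pytest.approx(100.0)
        assert np.isnan(rep.wilcoxon_p)  # undefined on all-zero diffs

    def test_shift_recovered_in_bias(self):
        a, b = self.tables(delta=2.5)
        rep = compare_tables(a, b, ["carb"], k=10)["carb"]
        assert rep.bias == pytest.approx(-2.5)
        assert rep.diff_summary["median"] == pytest.approx(-2.5)

    def test_key_mismatch_listed(self):
        a, b = self.tables()
        b = b.iloc[:-1]
        with pytest.raises(ConcordanceError, match="d59"):
            compare_tables(a, b, ["carb"])

    def test_report_serializes(self):
        a, b = self.tables(delta=1.0)
        rep = compare_tables(a, b, ["carb"], k=5)["carb"]
        d = rep.as_dict()
        assert d["n"] == 60 and len(d["top_extreme_dishes"]) == 5
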