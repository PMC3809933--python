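import math

import numpy as np
import pytest
from scipy import integrate, stats as sps

from chrysodiag import (
    CountTable,
    ExposureParams,
    chi2_goodness_of_fit,
    chi2_independence,
    exposure_rate,
    one_way_anova,
    proportion_table,
    ratio_comparison_matrix,
    tukey_kramer,
)
from chrysodiag.datasets import load_group_counts


def chi2_2x2_oracle(a, b, c, d):
    """Direct expected-counts arithmetic for a 2x2 table."""
    n = a + b + c + d
    stat = 0.0
    for obs, rt, ct in [
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ]:
        e = rt * ct / n
        stat += (obs - e) ** 2 / e
    return 1.0 - sps.chi2.cdf(stat, 1)


class TestChi2Independence:
    def test_bakerloo_vs_central_ratio(self):
        res = chi2_independence([[17, 11], [23, 30]])
        assert res.p_value == pytest.approx(0.138, abs=0.001)

    def test_jubilee_vs_outdoors_small_counts(self):
        res = chi2_independence([[10, 14], [2, 3]])
        assert res.p_value == pytest.approx(0.945, abs=0.001)

    def test_identical_proportions_give_zero_statistic(self):
        res = chi2_independence([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi2_independence([[0, 5], [0, 7]])

    def test_small_expected_counts_warn_but_compute(self):
        res = chi2_independence([[1, 2], [2, 1]])
        assert res.warnings

    def test_2x2_equals_squared_two_proportion_z(self):
        a, b, c, d = 17, 11, 23, 30
        p1, p2 = a / (a + b), c / (c + d)
        p = (a + c) / (a + b + c + d)
        z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / (a + b) + 1 / (c + d)))
        res = chi2_independence([[a, b], [c, d]])
        assert res.statistic == pytest.approx(z**2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_accept_reject_agrees_with_permutation_null(self, seed):
        # conditional (fixed-margins) null via hypergeometric sampling
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 16, size=(2, 2))
        while table.sum() > 60:
            table = rng.integers(1, 16, size=(2, 2))
        res = chi2_independence(table)
        r1, r2 = table.sum(axis=1)
        c1 = table.sum(axis=0)[0]
        draws = rng.hypergeometric(r1, r2, c1, size=100_000)
        n = table.sum()

        def stat(a):
            t = np.array(
                [a, r1 - a, c1 - a, r2 - (c1 - a)], dtype=float
            ).reshape(2, 2)
            e = np.outer(t.sum(1), t.sum(0)) / n
            return ((t - e) ** 2 / e).sum()

        obs = stat(table[0, 0])
        perm_p = np.mean([stat(a) >= obs - 1e-12 for a in draws])
        assert (res.p_value < 0.05) == (perm_p < 0.05) or abs(perm_p - 0.05) < 0.02


class TestGoodnessOfFit:
    def test_mating_counts_chrysogenum(self):
        assert chi2_goodness_of_fit([13, 11]).p_value == pytest.approx(0.68, abs=0.005)

    def test_mating_counts_rubens(self):
        assert chi2_goodness_of_fit([8, 14]).p_value == pytest.approx(0.20, abs=0.005)

    def test_perfect_fit(self):
        res = chi2_goodness_of_fit([12, 12])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_ratio_length_mismatch(self):
        with pytest.raises(ValueError, match="categories"):
            chi2_goodness_of_fit([1, 2, 3], [1, 1])

    def test_non_uniform_ratio(self):
        res = chi2_goodness_of_fit([30, 10], [3, 1])
        assert res.statistic == 0.0


class TestRatioComparisonMatrix:
    # every cell of the published pairwise-location matrix, by comparison:
    # rows Bakerloo, Central, Jubilee, Outdoors; columns Central, Jubilee,
    # Outdoors, St Mary's
    PRINTED = {
        "C:R": [
            [0.138, 0.171, 0.388, 0.382],
            [None, 0.887, 0.883, 0.858],
            [None, None, 0.945, 0.793],
            [None, None, None, 0.814],
        ],
        "C:O": [
            [0.056, 0.609, 0.084, 0.905],
            [None, 0.286, 0.004, 0.138],
            [None, None, 0.048, 0.613],
            [None, None, None, 0.138],
        ],
        "R:O": [
            [0.000, 0.020, 0.536, 0.304],
            [None, 0.310, 0.002, 0.065],
            [None, None, 0.026, 0.360],
            [None, None, None, 0.180],
        ],
        "C+R:O": [
            [0.000, 0.066, 0.098, 0.578],
            [None, 0.185, 0.000, 0.029],
            [None, None, 0.005, 0.342],
            [None, None, None, 0.058],
        ],
    }
    ORDER = ["Bakerloo Line", "Central Line", "Jubilee Line", "Outdoors", "St Mary's Hospital"]

    @pytest.fixture(scope="class")
    @staticmethod
    def matrices():
        order = TestRatioComparisonMatrix.ORDER
        counts = load_group_counts()
        reordered = CountTable(
            order,
            counts.col_labels,
            np.array(
                [counts.counts[counts.row_labels.index(r)] for r in order]
            ),
        )
        return ratio_comparison_matrix(reordered)

    @pytest.mark.parametrize("comparison", ["C:R", "C:O", "R:O", "C+R:O"])
    def test_full_published_matrix_reproduced(self, matrices, comparison):
        mat = matrices[comparison]
        for i, row_loc in enumerate(self.ORDER[:-1]):
            for j, col_loc in enumerate(self.ORDER[1:]):
                printed = self.PRINTED[comparison][i][j] if j >= i else None
                got = mat.loc[row_loc, col_loc]
                if printed is None:
                    assert math.isnan(got)  # lower triangle is empty as printed
                elif printed == 0.0:
                    assert got < 0.0005
                else:
                    assert got == pytest.approx(printed, abs=0.001)

    def test_each_cell_equals_direct_2x2_oracle(self, matrices):
        counts = load_group_counts().to_dataframe()
        mat = matrices["R:O"]
        for a in self.ORDER:
            for b in self.ORDER:
                if a >= b or b not in mat.columns or a not in mat.index:
                    continue
                got = mat.loc[a, b]
                if math.isnan(got):
                    continue
                exp = chi2_2x2_oracle(
                    counts.loc[a, "rubens"],
                    counts.loc[a, "other"],
                    counts.loc[b, "rubens"],
                    counts.loc[b, "other"],
                )
                assert got == pytest.approx(exp, rel=1e-9)

    def test_identical_locations_give_p_one(self):
        t = CountTable(["x", "y"], ["chrysogenum", "rubens", "other"],
                       np.array([[10, 20, 30], [10, 20, 30]]))
        mats = ratio_comparison_matrix(t)
        for mat in mats.values():
            assert mat.loc["x", "y"] == pytest.approx(1.0)

    def test_zero_margin_cell_is_undefined_marker(self):
        t = CountTable(["x", "y"], ["chrysogenum", "rubens", "other"],
                       np.array([[0, 5, 10], [0, 3, 12]]))
        mats = ratio_comparison_matrix(t, ["C:R"])
        assert math.isnan(mats["C:R"].loc["x", "y"])


class TestAnova:
    def test_identical_constant_groups(self):
        res = one_way_anova([[5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_sum_of_squares(self):
        groups = [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 7.0, 7.0]]
        flat = [x for g in groups for x in g]
        grand = sum(flat) / len(flat)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
        f_expected = (ssb / 2) / (ssw / 9)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f_expected, abs=1e-9)
        assert (res.df, 9) == (2, 9)

    def test_two_groups_f_equals_t_squared(self):
        g1, g2 = [3.1, 2.8, 3.5, 3.0], [2.2, 2.6, 2.0]
        t, _ = sps.ttest_ind(g1, g2)
        res = one_way_anova([g1, g2])
        assert res.statistic == pytest.approx(t**2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            one_way_anova([[1, 2], []])


def studentized_range_cdf_oracle(q, k, df):
    """Double-quadrature CDF of the studentized range (independent of the
    scipy distribution object used by the implementation)."""

    def inner(s):
        def f(z):
            return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (
                k - 1
            )

        val, _ = integrate.quad(f, -8, 8, limit=200)
        return k * val

    # density of s = chi_df / sqrt(df)
    def s_density(s):
        return (
            df ** (df / 2.0)
            / (math.gamma(df / 2.0) * 2 ** (df / 2.0 - 1))
            * s ** (df - 1)
            * math.exp(-df * s * s / 2.0)
        )

    val, _ = integrate.quad(lambda s: s_density(s) * inner(s), 0, 5, limit=200)
    return val


class TestTukeyKramer:
    def test_identical_groups_no_significance(self):
        res = tukey_kramer([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        assert all(c.q_statistic == 0.0 and not c.significant for c in res)

    def test_two_group_q_is_sqrt2_t(self):
        g1, g2 = [3.1, 2.8, 3.5, 3.0], [2.2, 2.6, 2.0, 2.9]
        t, _ = sps.ttest_ind(g1, g2)
        res = tukey_kramer([g1, g2])
        assert res[0].q_statistic == pytest.approx(math.sqrt(2) * abs(t), rel=1e-12)

    def test_quantile_matches_quadrature_oracle(self):
        qcrit = sps.studentized_range.ppf(0.95, 3, 12)
        assert studentized_range_cdf_oracle(qcrit, 3, 12) == pytest.approx(
            0.95, abs=1e-3
        )

    def test_unequal_sizes_use_kramer_se(self):
        g1, g2, g3 = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0], [6.0, 7.0]
        res = tukey_kramer([g1, g2, g3], labels=["a", "b", "c"])
        gs = [np.array(g) for g in (g1, g2, g3)]
        ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
        msw_val = ssw / (9 - 3)
        ab = next(c for c in res if (c.group_i, c.group_j) == ("a", "b"))
        se = math.sqrt(msw_val * 0.5 * (1 / 3 + 1 / 4))
        assert ab.q_statistic == pytest.approx(abs(np.mean(g1) - np.mean(g2)) / se)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            tukey_kramer([[1, 2], [3, 4]], alpha=1.5)


class TestExposure:
    def test_zero_count(self):
        assert exposure_rate(0, 500) == 0.0

    def test_arithmetic_oracle(self):
        # 53 colonies in 500 l at 0.5 l x 15 breaths: 7.5 * 53/500
        assert exposure_rate(53, 500) == pytest.approx(0.795)

    def test_scale_invariance(self):
        assert exposure_rate(53, 500) == exposure_rate(106, 1000)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            exposure_rate(-1, 500)

    def test_params_validated(self):
        with pytest.raises(ValueError):
            ExposureParams(tidal_volume_l=0)


class TestProportions:
    def test_survey_grand_totals(self):
        counts = load_group_counts()
        total = CountTable(
            ["Grand total"], counts.col_labels, counts.col_totals()[None, :]
        )
        pct = proportion_table(total)
        assert pct.loc["Grand total"].tolist() == [13.5, 15.1, 71.4]

    def test_single_cell_row(self):
        pct = proportion_table(CountTable(["r"], ["c"], np.array([[7]])))
        assert pct.loc["r", "c"] == 100.0

    def test_inverse_recovers_counts_within_rounding(self):
        counts = load_group_counts()
        pct = proportion_table(counts)
        totals = counts.row_totals()
        back = (pct.to_numpy() / 100.0) * totals[:, None]
        assert np.all(np.abs(back - counts.counts) <= totals[:, None] * 0.0005 + 1e-9)

    def test_zero_row_total_is_nan(self):
        pct = proportion_table(CountTable(["r"], ["a", "b"], np.array([[0, 0]])))
        assert pct.isna().all().all()
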