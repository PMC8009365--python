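"""Meta-analysis arithmetic against published worked examples and
closed-form oracles (direct formula evaluation, normal equations)."""

import numpy as np
import pytest
from scipy import stats

from biomeshift import (
    DiversificationInput,
    b_decline,
    diversification_rate,
    group_summary,
    load_table,
    meta_report,
    ols_fit,
    paired_one_tailed,
    shift_rate,
    specialists_pct,
    welch_one_tailed,
)

#: shift rates of the nine published single-biome-coding clades
SINGLE_RATES = [0.04, 0.08, 0.22, 0.11, 0.04, 0.01, 0.04, 0.02, 0.07]
#: the seven non-focal multiple-biome-coding clades
MULTI_NON_FOCAL = [0.31, 0.14, 0.7, 0.23, 0.44, 0.08, 0.48]


class TestShiftRate:
    @pytest.mark.parametrize("count,size,printed", [
        (23, 22, 1.04),  # printed value truncated from 1.0455
        (9, 7, 1.29),
        (40, 54, 0.74),
        (21, 29, 0.72),
    ])
    def test_agrees_with_printed_rates_at_printed_precision(self, count, size, printed):
        assert abs(shift_rate(count, size) - printed) <= 0.01

    def test_rytidosperma_a_reproduces_exactly_at_2dp(self):
        assert round(shift_rate(9, 7), 2) == 1.29

    def test_zero_shifts(self):
        assert shift_rate(0, 55) == 0.0

    def test_fractional_counts_floored(self):
        assert shift_rate(23.9, 22) == 23 / 22

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shift_rate(-1, 5)


class TestSpecialistsPct:
    @pytest.mark.parametrize("spec,size,pct", [(23, 51, 45), (12, 22, 55),
                                               (0, 10, 0)])
    def test_published_rows(self, spec, size, pct):
        assert round(specialists_pct(spec, size)) == pct

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            specialists_pct(6, 5)


class TestGroupSummary:
    def test_single_coding_median(self):
        assert group_summary(SINGLE_RATES).median == pytest.approx(0.04)

    def test_multiple_coding_median_and_q3(self):
        nz = [23 / 22, 40 / 54, 6 / 11, 6 / 11, 21 / 29, 7 / 13, 9 / 7,
              6 / 7, 40 / 51]
        g = group_summary(MULTI_NON_FOCAL + nz)
        assert round(g.median, 2) == 0.55
        assert round(g.q3, 2) == 0.75
        assert round(g.q1, 1) == 0.4

    def test_single_element(self):
        g = group_summary([0.3])
        assert g.median == g.q1 == g.q3 == 0.3

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.random(11)
        assert group_summary(x) == group_summary(rng.permutation(x))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            group_summary([0.1, np.nan])


class TestWelch:
    def test_published_comparison(self):
        r = welch_one_tailed(SINGLE_RATES, MULTI_NON_FOCAL)
        assert round(r.statistic, 2) == 3.20
        assert r.df_rounded == 7
        assert r.p < 0.01

    def test_identical_groups(self):
        r = welch_one_tailed([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(0.5)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(9), rng.random(7) + 0.3
        r = welch_one_tailed(a, b)
        se = np.sqrt(a.var(ddof=1) / 9 + b.var(ddof=1) / 7)
        t = (b.mean() - a.mean()) / se
        va, vb = a.var(ddof=1) / 9, b.var(ddof=1) / 7
        df = (va + vb) ** 2 / (va**2 / 8 + vb**2 / 6)
        assert r.statistic == pytest.approx(t, abs=1e-12)
        assert r.df == pytest.approx(df, abs=1e-12)
        assert r.p == pytest.approx(float(stats.t.sf(t, df)), abs=1e-12)

    def test_complementary_alternatives_sum_to_one(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(8), rng.random(8)
        assert welch_one_tailed(a, b).p + welch_one_tailed(b, a).p == \
            pytest.approx(1.0, abs=1e-10)


class TestPaired:
    def test_identical_vectors(self):
        r = paired_one_tailed([0.1, 0.2, 0.4], [0.1, 0.2, 0.4])
        assert r.statistic == 0.0 and r.p == 0.5

    def test_constant_positive_difference_does_not_crash(self):
        r = paired_one_tailed([0.1, 0.2, 0.3], [0.3, 0.4, 0.5])
        assert np.isinf(r.statistic) and r.p == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        s = rng.random(9)
        m = s + rng.normal(0.2, 0.1, 9)
        r = paired_one_tailed(s, m)
        d = m - s
        t = d.mean() / (d.std(ddof=1) / np.sqrt(9))
        assert r.statistic == pytest.approx(t, abs=1e-12)
        assert r.df == 8
        assert r.p == pytest.approx(float(stats.t.sf(t, 8)), abs=1e-12)


class TestOls:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r = ols_fit(x, 3 * x - 1)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(3.0)

    def test_orthogonal_response(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # symmetric: zero slope
        r = ols_fit(x, y)
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        x = rng.random(20)
        y = 2 + 0.5 * x + rng.normal(0, 0.2, 20)
        r = ols_fit(x, y)
        X = np.c_[np.ones(20), x]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.intercept == pytest.approx(beta[0], abs=1e-10)
        assert r.slope == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        assert r.r_squared == pytest.approx(r2, abs=1e-10)
        f = r2 / (1 - r2) * 18
        assert r.f_statistic == pytest.approx(f, abs=1e-8)

    def test_diagnostics_shapes(self):
        x = np.arange(6.0)
        r = ols_fit(x, x + np.r_[0.1, -0.1, 0.2, -0.2, 0.0, 0.1])
        assert r.residuals.shape == r.fitted.shape == (6,)
        assert len(r.qq[0]) == 6


class TestBDecline:
    @pytest.mark.parametrize("bm,bs,pct", [
        (0.72, 0.62, 14),  # published lower end of the 14-67% range
        (0.55, 0.18, 67),  # published upper end
    ])
    def test_published_range_endpoints(self, bm, bs, pct):
        assert b_decline(bm, bs).percent == pct

    def test_equal_rates_zero(self):
        assert b_decline(0.5, 0.5).b_decline == 0.0

    def test_zero_single_full_decline(self):
        for r in (0.1, 0.7, 1.3):
            assert b_decline(r, 0.0).b_decline == 1.0

    def test_zero_multiple_undefined(self):
        with pytest.raises(ValueError):
            b_decline(0.0, 0.1)


class TestDiversification:
    def test_published_stem_rate(self):
        r = diversification_rate(DiversificationInput(124, 10.21, "stem"))
        assert round(r, 2) == 0.47

    def test_published_crown_rate(self):
        r = diversification_rate(DiversificationInput(7, 2.00, "crown"))
        assert round(r, 2) == 0.63

    def test_two_species_crown_is_zero(self):
        assert diversification_rate(
            DiversificationInput(2, 5.0, "crown")
        ) == pytest.approx(0.0)

    def test_epsilon_zero_matches_log_formulas(self):
        assert diversification_rate(
            DiversificationInput(50, 8.0, "stem")
        ) == pytest.approx(np.log(50) / 8)
        assert diversification_rate(
            DiversificationInput(50, 8.0, "crown")
        ) == pytest.approx((np.log(50) - np.log(2)) / 8)

    def test_extinction_lowers_estimate(self):
        r0 = diversification_rate(DiversificationInput(50, 8.0, "stem"))
        r9 = diversification_rate(DiversificationInput(50, 8.0, "stem",
                                                       epsilon=0.9))
        assert r9 < r0


@pytest.fixture(scope="module")
def report():
    return meta_report()


class TestMetaReport:

    def test_group_summaries(self, report):
        assert report["summary_single"].median == pytest.approx(0.04)
        assert round(report["summary_multiple"].median, 2) == 0.55
        assert round(report["summary_multiple"].q3, 2) == 0.75

    def test_welch_against_non_focal_multiples(self, report):
        assert round(report["welch_non_focal"].statistic, 2) == 3.20
        assert report["welch_non_focal"].df_rounded == 7

    def test_paired_direction_and_significance(self, report):
        assert report["paired"].statistic > 0
        assert report["paired"].p < 0.01

    def test_b_decline_range(self, report):
        assert report["b_decline_min_pct"] == 14
        assert report["b_decline_max_pct"] == 67

    def test_tendency_display_matches_printed_column(self, report):
        t3 = load_table("table3")
        for _, row in t3.iterrows():
            assert report["tendency"][row["clade"]].display() == \
                row["tendency_printed"]

    def test_diversification_rates(self, report):
        assert round(report["diversification"]["Veronica"], 2) == 0.47
        assert round(report["diversification"]["Rytidosperma B"], 2) == 0.63

    def test_rate_declines_with_specialist_percentage(self, report):
        assert report["regression_rate_vs_specialists"].slope < 0
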