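"""Depth integration, regressions and the four-term metabolism budget."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from darkdic import (
    Constants,
    RateEstimate,
    build_station_budget,
    fit_yield,
    integrate_profile,
    nitrifier_combined_contribution,
    regress_rates,
    sulfur_scaling,
)
from darkdic.inhibition import compare_treatments


def ols_oracle(x, y):
    """Closed-form simple OLS with R2 and F, coded independently."""
    xc, yc = x - x.mean(), y - y.mean()
    slope = np.sum(xc * yc) / np.sum(xc ** 2)
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    ss_res, ss_tot = np.sum(resid ** 2), np.sum(yc ** 2)
    r2 = 1 - ss_res / ss_tot
    n = len(x)
    f = r2 / (1 - r2) * (n - 2)
    p = stats.f.sf(f, 1, n - 2)
    return slope, intercept, r2, f, p


def comparison_with(difference, significant=True):
    c = compare_treatments([10, 11, 12], [4, 5, 6])
    c.difference = difference
    c.significant = significant
    return c


class TestIntegrateProfile:
    def test_rectangle(self):
        # constant 2 nM d-1 over 100-300 m -> 400 umol m-2 d-1
        assert integrate_profile([100, 300], [2, 2]).value == pytest.approx(400.0)

    def test_triangle(self):
        assert integrate_profile([0, 100], [0, 10]).value == pytest.approx(500.0)

    def test_matches_fine_grid_riemann_sum(self, rng):
        z = np.sort(rng.uniform(20, 600, 15))
        r = np.abs(np.sin(z / 80.0)) * 5 + 0.5
        coarse = integrate_profile(z, r).value
        zf = np.arange(z[0], z[-1], 0.1)
        rf = np.interp(zf, z, r)
        riemann = np.sum(0.5 * (rf[1:] + rf[:-1]) * np.diff(zf))
        assert coarse == pytest.approx(riemann, rel=0.01)

    def test_linearity(self, rng):
        z = np.sort(rng.uniform(0, 500, 10))
        f, g = rng.uniform(0, 5, 10), rng.uniform(0, 5, 10)
        lhs = integrate_profile(z, 2 * f + 3 * g).value
        rhs = 2 * integrate_profile(z, f).value + 3 * integrate_profile(z, g).value
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_negative_clipping(self):
        # point rates are clipped before quadrature: the -2 endpoint becomes
        # 0, so the clipped integral is the trapezoid of (0, 2) over 100 m
        clipped = integrate_profile([0, 100], [-2, 2], clip_negative=True).value
        raw = integrate_profile([0, 100], [-2, 2]).value
        assert raw == pytest.approx(0.0)
        assert clipped == pytest.approx(100.0)

    def test_unsorted_depths_rejected(self):
        with pytest.raises(ValueError):
            integrate_profile([100, 50], [1, 1])


class TestRegressions:
    def test_exact_yield_line(self):
        x = np.array([2.0, 10.0, 25.0, 40.0])
        ao = [RateEstimate(mean=v, sd=0.1, n=3) for v in x]
        comps = [comparison_with(0.05 * v) for v in x]
        fit = fit_yield(ao, comps)
        assert fit.slope == pytest.approx(0.05, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_significance_filter(self):
        x = np.array([2.0, 10.0, 25.0, 40.0])
        ao = [RateEstimate(mean=v, sd=0.1, n=3) for v in x]
        comps = [comparison_with(0.05 * v, significant=(v > 5)) for v in x]
        assert fit_yield(ao, comps).n == 3
        assert fit_yield(ao, comps, include_only_significant=False).n == 4
        with pytest.raises(ValueError):
            fit_yield(ao[:2], comps[:2])

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(30):
            x = rng.uniform(0, 50, rng.integers(5, 15))
            y = 0.05 * x + rng.normal(0, 0.3, x.size)
            fit = regress_rates(x, y)
            slope, intercept, r2, f, p = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-8)
            assert fit.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-8)
            assert fit.f_statistic == pytest.approx(f, rel=1e-8)
            assert fit.p_value == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_anticorrelated_slope_negative(self, rng):
        x = np.linspace(0, 10, 20)
        y = -2 * x + rng.normal(0, 0.5, 20)
        fit = regress_rates(x, y)
        assert fit.slope < 0
        assert fit.p_value == pytest.approx(ols_oracle(x, y)[4], rel=1e-6)

    def test_null_r_squared_distribution(self, rng):
        # independent x, y: E[R2] = 1/(n-1)
        n, draws = 50, 400
        r2s = []
        for _ in range(draws):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r2s.append(regress_rates(x, y).r_squared)
        se = np.std(r2s, ddof=1) / np.sqrt(draws)
        assert abs(np.mean(r2s) - 1 / (n - 1)) < 3 * se

    def test_through_origin(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = regress_rates(x, 0.05 * x, through_origin=True)
        assert fit.slope == pytest.approx(0.05, rel=1e-12)
        assert fit.intercept == 0.0

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            regress_rates([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSulfurScaling:
    @pytest.mark.parametrize("ammonia,expected", [(58.0, 24), (15.0, 6),
                                                  (48.0, 20), (33.0, 14)])
    def test_printed_station_values(self, ammonia, expected):
        assert round(sulfur_scaling(ammonia)) == expected

    def test_null_input(self):
        assert sulfur_scaling(0.0) == 0.0

    def test_zero_yield_rejected(self):
        with pytest.raises(ValueError):
            sulfur_scaling(10.0, yield_aoa_measured=0.0)

    @given(ammonia=st.floats(0.1, 500))
    @settings(max_examples=50, deadline=None)
    def test_upper_bound_ratio(self, ammonia):
        # with yield_sox at its maximum 0.35 and measured yield 0.05 the
        # sulfur:ammonia ratio is exactly 7/17
        assert sulfur_scaling(ammonia) / ammonia == pytest.approx(7 / 17, rel=1e-12)


class TestStationBudget:
    def test_additivity_and_percentages(self):
        b = build_station_budget("Stn5", total=234.0, ammonia_fuelled=58.0,
                                 nitrite_oxidation_integrated=82.0 / 0.036,
                                 hetero_production_integrated=95.0 / 0.10)
        assert b.all_metabolisms == pytest.approx(
            b.ammonia_fuelled + b.nitrite_fuelled + b.sulfur_fuelled + b.heterotrophic,
            rel=1e-12)
        r = b.rounded()
        assert r["all_metabolisms"] == 259
        assert r["all_metabolisms_pct"] == 111
        assert r["ammonia_fuelled_pct"] == 25

    def test_zero_budget_flags_percentages(self):
        b = build_station_budget("Z", 0.0, 0.0, 0.0, 0.0)
        assert b.all_metabolisms == 0.0
        assert all(np.isnan(v) for v in b.percentages.values())

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            build_station_budget("X", -1.0, 0.0, 0.0, 0.0)

    @given(
        total=st.floats(1, 2000), amm=st.floats(0, 500),
        nox=st.floats(0, 5000), het=st.floats(0, 5000),
    )
    @settings(max_examples=100, deadline=None)
    def test_rounding_discrepancy_bounded(self, total, amm, nox, het):
        b = build_station_budget("S", total, amm, nox, het)
        r = b.rounded()
        component_sum = (r["ammonia_fuelled"] + r["nitrite_fuelled"]
                         + r["sulfur_fuelled"] + r["heterotrophic"])
        assert abs(component_sum - r["all_metabolisms"]) <= 2


class TestNitrifierContribution:
    def test_single_depth_share(self):
        # ammonia-fuelled 2, nitrite-estimated 1, total 6 nM d-1 -> 50%
        out = nitrifier_combined_contribution(
            [2.0], [1.0 / 0.036], [6.0], ["upper_mesopelagic"])
        mean, sd, n = out["upper_mesopelagic"]
        assert mean == pytest.approx(50.0, rel=1e-12)
        assert sd == 0.0 and n == 1

    def test_zero_total_excluded(self):
        out = nitrifier_combined_contribution(
            [2.0, 1.0], [0.0, 0.0], [6.0, 0.0],
            ["euphotic", "euphotic"])
        assert out["euphotic"][2] == 1

    def test_zone_grouping(self):
        out = nitrifier_combined_contribution(
            [1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [10.0, 10.0, 10.0],
            ["euphotic", "euphotic", "upper_mesopelagic"])
        assert out["euphotic"][0] == pytest.approx(15.0)
        assert out["upper_mesopelagic"][0] == pytest.approx(30.0)
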