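"""Trend statistics: OLS against a statsmodels oracle, piecewise fits,
pixel-wise maps against a per-pixel loop, compositing and the paired t."""

import math

import numpy as np
import pytest

from swampflux.trends import (
    LinearTrend,
    PiecewiseTrend,
    amj_composite,
    ols_trend,
    paired_t,
    piecewise_trend,
    pixelwise_trends,
    stratum_means,
)

YEARS_14 = list(range(2007, 2011)) + list(range(2015, 2025))


class TestOlsTrend:
    def test_noiseless_line_recovered_exactly(self):
        years = list(range(2007, 2017))
        values = [2.0 * y + 5.0 for y in years]
        fit = ols_trend(years, values)
        assert fit.slope == pytest.approx(2.0)
        assert fit.slope_ci_high - fit.slope_ci_low == pytest.approx(0.0)
        assert fit.p_value == 0.0

    def test_constant_series_flat(self):
        fit = ols_trend([1, 2, 3, 4], [7.0] * 4)
        assert fit.slope == 0.0
        assert fit.p_value == 1.0

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        values = 1528.0 * np.array(YEARS_14) + rng.normal(0, 3000, len(YEARS_14))
        fit = ols_trend(YEARS_14, values)
        res = sm.OLS(values, sm.add_constant(np.array(YEARS_14, dtype=float))).fit()
        assert fit.slope == pytest.approx(res.params[1], rel=1e-10)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-10)
        assert fit.p_value == pytest.approx(res.pvalues[1], rel=1e-8)
        lo, hi = res.conf_int(alpha=0.05)[1]
        assert fit.slope_ci_low == pytest.approx(lo, rel=1e-8)
        assert fit.slope_ci_high == pytest.approx(hi, rel=1e-8)

    def test_ci_coverage_on_gap_year_pattern(self):
        """95% CI covers the true slope ~95% of the time on the 14-year
        observation pattern with a 2011-2014 gap."""
        rng = np.random.default_rng(42)
        true_slope = 1528.0
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            values = true_slope * np.array(YEARS_14) + rng.normal(0, 3000, len(YEARS_14))
            fit = ols_trend(YEARS_14, values)
            hits += fit.slope_ci_low <= true_slope <= fit.slope_ci_high
        assert hits / n_rep == pytest.approx(0.95, abs=0.03)

    @pytest.mark.parametrize("years,values", [([1, 2], [1.0, 2.0]), ([1, 1, 2], [1, 2, 3.0])])
    def test_invalid_inputs_rejected(self, years, values):
        with pytest.raises(ValueError):
            ols_trend(years, values)

    def test_estimator_interface(self):
        est = LinearTrend().fit([1, 2, 3, 4], [2, 4, 6, 8.0])
        assert est.slope_ == pytest.approx(2.0)
        assert np.allclose(est.predict([5, 6]), [10.0, 12.0])
        assert LinearTrend(**est.get_params()).get_params() == est.get_params()


class TestPiecewiseTrend:
    def test_v_shape_exact_recovery(self):
        years = list(range(2000, 2021))
        values = [abs(y - 2010) * 3.0 + 1.0 for y in years]
        fit = piecewise_trend(years, values)
        assert fit.breakpoint_year == 2010
        assert fit.slope_pre == pytest.approx(-3.0)
        assert fit.slope_post == pytest.approx(3.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_pure_line_equal_segment_slopes(self):
        years = list(range(2007, 2017))
        values = [1.5 * y for y in years]
        fit = piecewise_trend(years, values)
        line_fit = LinearTrend().fit(years, values)
        assert fit.slope_pre == pytest.approx(fit.slope_post, abs=1e-6)
        assert fit.rss == pytest.approx(line_fit.rss_, abs=1e-9)

    def test_piecewise_rss_never_exceeds_line_rss(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = rng.normal(0, 1, len(YEARS_14))
            pw = piecewise_trend(YEARS_14, values)
            line = LinearTrend().fit(YEARS_14, values)
            assert pw.rss <= line.rss_ + 1e-9

    def test_breakpoint_strictly_interior(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, len(YEARS_14))
        fit = piecewise_trend(YEARS_14, values)
        assert YEARS_14[0] < fit.breakpoint_year < YEARS_14[-1]

    def test_breakpoint_recovery_under_noise(self):
        """Drying-to-wetting break near 2017 recovered within +/-1 year in
        >=90% of replicates at signal-to-noise ratio 4."""
        rng = np.random.default_rng(7)
        true_break = 2017
        signal = np.array([
            -800.0 * (y - true_break) if y <= true_break else 1200.0 * (y - true_break)
            for y in YEARS_14
        ])
        sd = signal.std() / 4.0  # amplitude SNR (signal SD / noise SD) = 4
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            fit = piecewise_trend(YEARS_14, signal + rng.normal(0, sd, len(YEARS_14)))
            hits += abs(fit.breakpoint_year - true_break) <= 1
        assert hits / n_rep >= 0.90

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            piecewise_trend([1, 2, 3, 4, 5], [1, 2, 3, 4, 5.0])


class TestPixelwiseTrends:
    def test_equals_per_pixel_ols_loop(self):
        rng = np.random.default_rng(3)
        years = YEARS_14
        stack = [rng.normal(0.5, 0.05, (5, 5)) for _ in years]
        slope, p, _ = pixelwise_trends(stack, years)
        for r in range(5):
            for c in range(5):
                fit = ols_trend(years, [g[r, c] for g in stack])
                assert slope[r, c] == pytest.approx(fit.slope, rel=1e-8)
                assert p[r, c] == pytest.approx(fit.p_value, rel=1e-6)

    def test_all_constant_stack_no_significant_pixels(self):
        stack = [np.full((4, 4), 0.5) for _ in range(6)]
        _, _, summary = pixelwise_trends(stack, list(range(6)))
        assert summary["frac_significant_increase"] == 0.0
        assert summary["frac_significant_decrease"] == 0.0

    def test_mixture_fraction_matches_expectation(self):
        """10% of pixels get a strong positive trend; the detected positive
        fraction sits near 0.10 + alpha/2 * 0.90 (false positives split
        evenly by sign)."""
        rng = np.random.default_rng(4)
        years = np.arange(20)
        n_pix = 60 * 60
        strong = np.zeros((60, 60), dtype=bool)
        strong.ravel()[: n_pix // 10] = True
        stack = []
        for t in years:
            grid = rng.normal(0, 1.0, (60, 60))
            grid[strong] += 2.0 * t  # overwhelming trend
            stack.append(grid)
        _, _, summary = pixelwise_trends(stack, years, alpha=0.05)
        expected = 0.10 + 0.025 * 0.90
        se = math.sqrt(expected * (1 - expected) / n_pix)
        assert abs(summary["frac_significant_increase"] - expected) < 3 * se

    def test_pixels_with_few_years_excluded(self):
        stack = [np.full((2, 2), np.nan) for _ in range(5)]
        for i in range(5):
            stack[i][0, 0] = float(i)
        stack[0][1, 1] = 1.0
        stack[1][1, 1] = 2.0  # only two valid years -> excluded
        slope, p, summary = pixelwise_trends(stack, list(range(5)))
        assert np.isfinite(slope[0, 0])
        assert np.isnan(slope[1, 1])
        assert summary["n_pixels"] == 1.0


class TestAmjComposite:
    def test_mean_of_amj_months(self):
        monthly = {(2007, m): np.full((2, 2), v)
                   for m, v in zip((4, 5, 6), (0.4, 0.5, 0.6))}
        comps, avail = amj_composite(monthly)
        assert comps[2007][0, 0] == pytest.approx(0.5)
        assert np.all(avail == 1.0)

    def test_low_availability_pixel_masked(self):
        rng = np.random.default_rng(5)
        monthly = {}
        for year in range(2007, 2017):
            for m in (4, 5, 6):
                monthly[(year, m)] = np.full((2, 2), 0.5)
        # pixel (0,0): drop 7 of 30 slots -> 76.7% availability < 80%
        for (year, m) in list(monthly)[:7]:
            monthly[(year, m)] = monthly[(year, m)].copy()
            monthly[(year, m)][0, 0] = np.nan
        comps, avail = amj_composite(monthly, availability_threshold=0.8)
        assert avail[0, 0] == pytest.approx(23 / 30)
        assert all(np.isnan(c[0, 0]) for c in comps.values())
        assert all(np.isfinite(c[1, 1]) for c in comps.values())

    def test_fully_available_constant_pixel_unchanged(self):
        monthly = {(y, m): np.full((2, 2), 0.37)
                   for y in (2007, 2008) for m in (4, 5, 6)}
        comps, _ = amj_composite(monthly)
        assert all(c[0, 0] == pytest.approx(0.37) for c in comps.values())

    def test_non_amj_months_ignored_and_empty_rejected(self):
        with pytest.raises(ValueError):
            amj_composite({(2007, 1): np.zeros((2, 2))})


class TestStrataAndPairedT:
    def test_uniform_evi_same_in_all_strata(self):
        freq = np.array([[0, 7], [14, 14]])
        evi = {2007: np.full((2, 2), 0.5), 2008: np.full((2, 2), 0.5)}
        out = stratum_means(evi, freq, 14)
        for name in ("all", "swamp", "terra_firme"):
            assert out[name][2007] == pytest.approx(0.5)

    def test_imposed_stratum_means_recovered(self):
        freq = np.array([[14, 14], [0, 0]])
        grid = np.array([[0.45, 0.45], [0.50, 0.50]])
        out = stratum_means({2007: grid}, freq, 14)
        assert out["swamp"][2007] == pytest.approx(0.45)
        assert out["terra_firme"][2007] == pytest.approx(0.50)

    def test_empty_stratum_warns_and_omits(self):
        freq = np.zeros((2, 2), dtype=int)  # no always-flooded pixels
        with pytest.warns(UserWarning):
            out = stratum_means({2007: np.full((2, 2), 0.5)}, freq, 14)
        assert "swamp" not in out

    def test_identical_series_t_zero_p_one(self):
        a = [0.5, 0.6, 0.7, 0.8]
        assert paired_t(a, a) == (0.0, 1.0)

    def test_constant_shift_reported_as_limit(self):
        a = [0.5, 0.6, 0.7]
        t, p = paired_t(a, [x + 0.05 for x in a])
        assert t == -math.inf and p == 0.0

    def test_power_on_small_swamp_deficit(self):
        """A 0.05 EVI deficit with 0.01 SD over 14 years is detected at
        alpha=0.05 in >=99% of replicates."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            tf = rng.normal(0.50, 0.01, 14)
            swamp = tf - 0.05 + rng.normal(0, 0.01, 14)
            t, p = paired_t(swamp.tolist(), tf.tolist())
            hits += (p < 0.05) and (t < 0)
        assert hits / n_rep >= 0.99
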