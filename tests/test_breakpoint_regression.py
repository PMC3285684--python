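"""Broken-stick fits, exhaustive breakpoint search and model comparison."""

import numpy as np
import pytest
from scipy import stats

from betabreak import (
    compare_to_linear,
    fit_piecewise,
    search_breakpoint,
    segment_summary,
)


def broken_stick(x, bp, intercept, slope_below, slope_above):
    return np.where(
        x <= bp, intercept + slope_below * (x - bp), intercept + slope_above * (x - bp)
    )


class TestFitPiecewise:
    def test_pure_line_gives_equal_slopes_and_zero_rse(self):
        x = np.arange(20.0)
        y = 2.0 * x + 1.0
        fit = fit_piecewise(x, y, breakpoint=9)
        assert fit.slope_below == pytest.approx(2.0, abs=1e-10)
        assert fit.slope_above == pytest.approx(2.0, abs=1e-10)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-10)

    def test_recovers_constructed_slopes_exactly(self):
        # slope magnitudes of the turnover-component latitudinal fit
        x = np.linspace(10, 60, 101)
        y = broken_stick(x, 37, 0.46, 0.002, -0.016)
        fit = fit_piecewise(x, y, breakpoint=37)
        assert fit.slope_below == pytest.approx(0.002, abs=1e-12)
        assert fit.slope_above == pytest.approx(-0.016, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_residual_se_matches_direct_rss_arithmetic(self, rng):
        x = rng.uniform(0, 50, 40)
        y = rng.normal(size=40)
        fit = fit_piecewise(x, y, breakpoint=25)
        pred = fit.predict(x)
        rss = float(((y - pred) ** 2).sum())
        assert fit.rss == pytest.approx(rss, rel=1e-9)
        assert fit.residual_se == pytest.approx(np.sqrt(rss / (40 - 4)), rel=1e-9)

    def test_discontinuous_mode_fits_independent_segments(self, rng):
        x = np.concatenate([np.linspace(0, 10, 20), np.linspace(11, 20, 20)])
        y = np.where(x <= 10, 1.0 + 0.5 * x, 30.0 - 2.0 * x)
        fit = fit_piecewise(x, y, breakpoint=10, mode="discontinuous")
        assert fit.slope_below == pytest.approx(0.5, abs=1e-10)
        assert fit.slope_above == pytest.approx(-2.0, abs=1e-10)
        assert fit.intercept_above == pytest.approx(30.0, abs=1e-8)

    def test_rejects_starved_segment(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_piecewise(x, x, breakpoint=0)


class TestSearchBreakpoint:
    def test_noiseless_recovery_is_exact(self):
        x = np.linspace(5, 65, 200)
        y = broken_stick(x, 37, 0.46, 0.002, -0.016)
        assert search_breakpoint(x, y).breakpoint == 37

    def test_equals_brute_force_argmin(self, rng):
        x = rng.uniform(0, 40, 60)
        y = rng.normal(size=60) + 0.05 * x
        best = search_breakpoint(x, y, min_seg=5)
        fits = [
            fit_piecewise(x, y, bp)
            for bp in range(int(x.min()) + 1, int(np.ceil(x.max())))
            if min((x <= bp).sum(), (x > bp).sum()) >= 5
        ]
        oracle = min(fits, key=lambda f: f.residual_se)
        assert best.breakpoint == oracle.breakpoint
        assert best.residual_se == pytest.approx(oracle.residual_se)

    def test_pure_linear_ties_resolve_to_smallest_candidate(self):
        x = np.linspace(0, 30, 100)
        y = 1.0 + 0.3 * x
        fit = search_breakpoint(x, y, min_seg=5)
        admissible = [
            bp for bp in range(1, 30) if min((x <= bp).sum(), (x > bp).sum()) >= 5
        ]
        assert fit.breakpoint == min(admissible)

    def test_piecewise_r2_never_below_linear(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 50, 80)
            y = rng.normal(size=80) + rng.uniform(-0.1, 0.1) * x
            fit = search_breakpoint(x, y)
            comp = compare_to_linear(x, y, fit)
            assert comp.r2_piecewise >= comp.r2_linear - 1e-12

    def test_invariant_to_shifting_response(self, rng):
        x = rng.uniform(0, 50, 80)
        y = rng.normal(size=80) + 0.02 * x
        a = search_breakpoint(x, y)
        b = search_breakpoint(x, y + 100.0)
        assert a.breakpoint == b.breakpoint
        assert a.slope_below == pytest.approx(b.slope_below)
        ca = compare_to_linear(x, y, a)
        cb = compare_to_linear(x, y + 100.0, b)
        assert ca.f_statistic == pytest.approx(cb.f_statistic, rel=1e-9)

    def test_linear_world_rarely_flags_a_breakpoint(self):
        """Under a purely linear truth the post-search F test stays
        non-significant in at least 90% of replicates (the search inflates
        it only mildly because candidate fits are highly correlated)."""
        rng = np.random.default_rng(11)
        n, rejections = 188, 0
        for _ in range(100):
            x = np.sort(rng.uniform(2, 62, n))
            y = 0.5 + 0.002 * x + rng.normal(0, 0.05, n)
            fit = search_breakpoint(x, y)
            rejections += compare_to_linear(x, y, fit).p_value < 0.05
        assert rejections <= 10

    def test_no_admissible_candidate_raises(self):
        x = np.array([1.0, 1.5, 30.0, 30.5, 31.0])
        with pytest.raises(ValueError, match="admissible"):
            search_breakpoint(x, x, min_seg=5)


class TestCompareToLinear:
    def test_df_convention_matches_printed_values(self, rng):
        # the study's 321 regional cells give F on (2, 317) df
        x = rng.uniform(0, 60, 321)
        y = broken_stick(x, 37, 0.46, 0.002, -0.016) + rng.normal(0, 0.1, 321)
        fit = search_breakpoint(x, y)
        comp = compare_to_linear(x, y, fit)
        assert (comp.df_num, comp.df_den) == (2, 317)

    def test_degenerate_stick_gives_f_zero_p_one(self):
        x = np.linspace(0, 30, 50)
        y = 2.0 + 0.5 * x
        fit = fit_piecewise(x, y, breakpoint=15)
        comp = compare_to_linear(x, y, fit)
        assert comp.f_statistic == 0.0
        assert comp.p_value == 1.0

    def test_exact_piecewise_fit_flags_infinite_f(self):
        x = np.linspace(0, 30, 50)
        y = broken_stick(x, 15, 1.0, 0.5, -0.5)
        fit = fit_piecewise(x, y, breakpoint=15)
        comp = compare_to_linear(x, y, fit)
        assert comp.exact_fit and np.isinf(comp.f_statistic) and comp.p_value == 0.0

    def test_f_matches_hand_rss_arithmetic(self, rng):
        x = rng.uniform(0, 40, 30)
        y = rng.normal(size=30) + 0.1 * x
        fit = fit_piecewise(x, y, breakpoint=20)
        comp = compare_to_linear(x, y, fit)
        lin = np.polyfit(x, y, 1)
        rss_lin = float(((y - np.polyval(lin, x)) ** 2).sum())
        f_hand = ((rss_lin - fit.rss) / 2) / (fit.rss / (30 - 4))
        assert comp.f_statistic == pytest.approx(max(f_hand, 0.0), rel=1e-9)


class TestSegmentSummary:
    def test_constant_values_have_zero_width(self):
        out = segment_summary(np.ones(20), np.arange(20.0), 9.5)
        assert out["below"].ci_half_width == 0.0
        assert out["above"].ci_half_width == 0.0

    def test_t_interval_hand_example(self):
        # one segment holding {1,2,3}: mean 2, half-width t_{.975,2}/sqrt(3)
        values = np.array([1.0, 2.0, 3.0, 5.0, 5.0])
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0])
        out = segment_summary(values, x, 5.0)
        assert out["below"].mean == pytest.approx(2.0)
        assert out["below"].ci_half_width == pytest.approx(
            stats.t.ppf(0.975, 2) / np.sqrt(3), rel=1e-9
        )
        assert out["below"].ci_half_width == pytest.approx(2.484, abs=1e-3)

    def test_counts_partition_the_data(self, rng):
        x = rng.uniform(0, 50, 37)
        out = segment_summary(rng.normal(size=37), x, 25.0)
        assert out["below"].n + out["above"].n == 37

    def test_single_point_segment_is_flagged(self):
        out = segment_summary(np.array([1.0, 2.0, 3.0, 9.0]), np.array([1.0, 2, 3, 40]), 30)
        assert out["above"].degenerate and np.isnan(out["above"].ci_half_width)
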