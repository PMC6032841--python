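"""Proportion series, segmented regression, Davies test, periods."""

import numpy as np
import pytest

from pinkfoot.assign import StrategyTable, assign_strategies
from pinkfoot.core import STRATEGIES, Strategy
from pinkfoot.trends import (
    annual_proportions,
    davies_test,
    derive_periods,
    fit_piecewise,
)


def _table(entries):
    t = StrategyTable()
    for bid, year, label in entries:
        t[(bid, year)] = Strategy.from_label(label)
    return t


class TestAnnualProportions:
    def test_simple_tally(self):
        entries = [(f"B{i}", 1995, "Ju-Fr") for i in range(6)]
        entries += [(f"C{i}", 1995, "Ju") for i in range(4)]
        series = annual_proportions(_table(entries))
        labels = [s.label for s in STRATEGIES]
        row = dict(zip(labels, series.proportions[0]))
        assert row["Ju-Fr"] == pytest.approx(0.6)
        assert row["Ju"] == pytest.approx(0.4)
        assert series.n[0] == 10

    def test_single_strategy_indicator(self):
        series = annual_proportions(_table([("B1", 2000, "Fl"), ("B2", 2000, "Fl")]))
        j = [s.label for s in STRATEGIES].index("Fl")
        assert series.proportions[0, j] == 1.0
        assert series.proportions[0].sum() == pytest.approx(1.0)

    def test_rows_sum_to_one_on_simulation(self, small_dataset):
        cfg, birds, resightings, _, _ = small_dataset
        table = assign_strategies(resightings, birds, window=cfg.window, excluded_seasons=())
        series = annual_proportions(table)
        assert np.allclose(series.proportions.sum(axis=1), 1.0, atol=1e-12)
        # counting oracle: brute-force tally per (year, strategy)
        for i, year in enumerate(series.years):
            for j, s in enumerate(STRATEGIES):
                count = sum(
                    1 for (b, y), st in table.items() if y == year and st == s
                )
                assert series.proportions[i, j] == pytest.approx(count / series.n[i])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            annual_proportions(StrategyTable())


class TestPiecewiseFit:
    def test_recovers_constructed_breakpoint(self):
        x = np.arange(1991, 2016, dtype=float)
        y = np.where(x <= 2007, 0.01 * (x - 1991), 0.16 + 0.05 * (x - 2007))
        fit = fit_piecewise(x, y, max_breaks=2, n_boot=50, seed=0)
        assert fit.n_breakpoints == 1
        assert fit.breakpoints[0] == pytest.approx(2007.0, abs=0.5)
        assert fit.segment_slopes[0] == pytest.approx(0.01, abs=1e-6)
        assert fit.segment_slopes[1] == pytest.approx(0.05, abs=1e-6)

    def test_linear_data_selects_zero_breaks_and_matches_ols(self):
        x = np.arange(1991, 2016, dtype=float)
        y = 0.3 + 0.01 * (x - 1991)
        fit = fit_piecewise(x, y, max_breaks=2, n_boot=0)
        assert fit.n_breakpoints == 0
        b1, b0 = np.polyfit(x, y, 1)
        assert fit.coef[1] == pytest.approx(b1, abs=1e-10)
        assert fit.coef[0] == pytest.approx(b0, abs=1e-8)

    def test_zero_max_breaks_is_ols(self):
        rng = np.random.default_rng(0)
        x = np.arange(1991, 2016, dtype=float)
        y = 0.3 + 0.01 * (x - 1991) + rng.normal(0, 0.05, 25)
        fit = fit_piecewise(x, y, max_breaks=0, n_boot=0)
        b1, b0 = np.polyfit(x, y, 1)
        assert fit.coef[1] == pytest.approx(b1, abs=1e-10)

    def test_constant_series_zero_breaks(self):
        x = np.arange(2000, 2015, dtype=float)
        fit = fit_piecewise(x, np.full(15, 0.2), max_breaks=1, n_boot=0)
        assert fit.n_breakpoints == 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_piecewise(np.arange(4.0), np.arange(4.0), max_breaks=1)

    def test_noise_shrinks_error(self):
        # breakpoint estimator consistency as noise -> 0
        x = np.arange(1991, 2016, dtype=float)
        signal = np.where(x <= 2003, 0.0, 0.04 * (x - 2003))
        rng = np.random.default_rng(5)
        noise_big = rng.normal(0, 0.05, 25)
        err = {}
        for sigma, noise in [(0.05, noise_big), (0.0, np.zeros(25))]:
            fit = fit_piecewise(x, signal + noise, max_breaks=1, n_boot=0)
            err[sigma] = abs(fit.breakpoints[0] - 2003) if fit.breakpoints else np.inf
        assert err[0.0] <= err[0.05] + 1e-9
        assert err[0.0] < 0.2

    def test_bootstrap_ci_covers_constructed_truth(self):
        # single-break series with mild noise: the 95% CI should usually
        # cover the true location (checked over a modest seed battery)
        x = np.arange(1991, 2016, dtype=float)
        signal = np.where(x <= 2004, 0.0, 0.05 * (x - 2004))
        hits = trials = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = signal + rng.normal(0, 0.02, 25)
            fit = fit_piecewise(x, y, max_breaks=1, n_boot=150, seed=seed)
            if fit.n_breakpoints != 1:
                continue
            lo, hi = fit.breakpoint_cis[0]
            trials += 1
            hits += lo - 1e-9 <= 2004 <= hi + 1e-9
        assert trials >= 25
        assert hits / trials >= 0.85


class TestDaviesTest:
    def test_constant_response_p_one(self):
        x = np.arange(1991, 2016, dtype=float)
        assert davies_test(x, np.zeros(25)) == 1.0
        assert davies_test(x, np.full(25, 0.3)) == 1.0

    def test_strong_break_detected(self):
        x = np.arange(1991, 2016, dtype=float)
        rng = np.random.default_rng(1)
        y = np.where(x <= 2003, 0.0, 5.0 * (x - 2003)) + rng.normal(0, 1, 25)
        assert davies_test(x, y) < 0.001

    def test_affine_invariance(self):
        x = np.arange(1991, 2016, dtype=float)
        rng = np.random.default_rng(3)
        y = 1 + 0.1 * x + rng.normal(0, 1, 25)
        p1 = davies_test(x, y)
        p2 = davies_test(2 * x - 1000.0, 3 * y + 5.0)
        assert p1 == pytest.approx(p2, abs=1e-6)

    def test_candidate_reduction_warns(self):
        x = np.arange(10, dtype=float)
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="reducing"):
            davies_test(x, rng.normal(size=10), k_candidates=10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            davies_test(np.arange(5.0), np.arange(5.0))


class TestDerivePeriods:
    class _Fit:
        def __init__(self, breakpoints, x_range=(1991.0, 2015.0)):
            self.breakpoints = breakpoints
            self.x_range = x_range

    def test_published_style_pooling(self):
        fits = [self._Fit([1996.5, 1996.8]), self._Fit([2006.6]), self._Fit([2010.4])]
        assert derive_periods(fits) == [
            (1991, 1996),
            (1997, 2006),
            (2007, 2010),
            (2011, 2015),
        ]

    def test_no_breakpoints_single_interval(self):
        assert derive_periods([self._Fit([])]) == [(1991, 2015)]

    def test_single_breakpoint_rounding(self):
        assert derive_periods([self._Fit([2000.2])]) == [(1991, 2000), (2001, 2015)]

    def test_periods_partition_span(self):
        fits = [self._Fit([1995.2, 2001.9, 2008.4])]
        periods = derive_periods(fits)
        assert periods[0][0] == 1991 and periods[-1][1] == 2015
        for (a, b), (c, d) in zip(periods, periods[1:]):
            assert c == b + 1
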