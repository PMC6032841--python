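"""Region-use proportions, covariate scaling and driver GLMs."""

import numpy as np
import pandas as pd
import pytest

from pinkfoot.core import STRATEGIES, Region
from pinkfoot.drivers import (
    downscale_land_use,
    fit_driver_model,
    proportion_staying,
    proportion_using_region,
    scale_covariate,
)
from pinkfoot.trends import ProportionSeries

_LABELS = [s.label for s in STRATEGIES]


def _series(rows):
    """rows: list of (year, {label: prop})"""
    years = np.array([y for y, _ in rows])
    mat = np.zeros((len(rows), 7))
    for i, (_, d) in enumerate(rows):
        for lab, p in d.items():
            mat[i, _LABELS.index(lab)] = p
    return ProportionSeries(years=years, proportions=mat, n=np.full(len(rows), 100))


class TestRegionUse:
    def test_sum_over_containing_strategies(self):
        s = _series([(2000, {"Ju": 0.4, "Ju-Fr": 0.3, "Fr": 0.2, "Fr-Fl": 0.1})])
        assert proportion_using_region(s, Region.FR)[2000] == pytest.approx(0.6)
        assert proportion_using_region(s, Region.JU)[2000] == pytest.approx(0.7)

    def test_full_subset_strategy_counts_everywhere(self):
        s = _series([(2000, {"Ju-Fr-Fl": 1.0})])
        for region in Region:
            assert proportion_using_region(s, region)[2000] == 1.0

    def test_staying_is_single_region_strategy(self):
        s = _series([(2000, {"Ju": 0.25, "Ju-Fr": 0.75})])
        assert proportion_staying(s, Region.JU)[2000] == pytest.approx(0.25)

    def test_matches_bruteforce_subset_sum(self):
        rng = np.random.default_rng(0)
        mat = rng.dirichlet(np.ones(7), size=5)
        s = ProportionSeries(
            years=np.arange(2000, 2005), proportions=mat, n=np.full(5, 50)
        )
        for region in Region:
            expected = np.array(
                [
                    sum(
                        mat[i, j]
                        for j, strat in enumerate(STRATEGIES)
                        if region in strat.regions
                    )
                    for i in range(5)
                ]
            )
            got = proportion_using_region(s, region).to_numpy()
            assert np.allclose(got, expected)
            # always at least the single-region share
            assert np.all(got >= proportion_staying(s, region).to_numpy() - 1e-15)


class TestScaleCovariate:
    def test_symmetric_case(self):
        assert np.allclose(scale_covariate([0, 5, 10]), [-1, 0, 1])

    def test_skewed_case_endpoints_not_unit(self):
        assert np.allclose(scale_covariate([0, 0, 10]), [-2 / 3, -2 / 3, 4 / 3])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale_covariate([3, 3, 3])

    def test_mean_zero_range_two(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(50, 20, size=rng.integers(3, 30))
            s = scale_covariate(x)
            assert abs(s.mean()) < 1e-12
            assert s.max() - s.min() == pytest.approx(2.0, abs=1e-12)


class TestDownscale:
    def test_proportionality(self):
        assert downscale_land_use(50, 100, 125) == pytest.approx(40.0)

    def test_identity_when_units_match(self):
        assert downscale_land_use(77.5, 300, 300) == pytest.approx(77.5)

    def test_roundtrip(self):
        v = downscale_land_use(downscale_land_use(50, 100, 125), 125, 100)
        assert v == pytest.approx(50.0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            downscale_land_use(50, 0, 125)


def _cov(n=25, seed=0):
    rng = np.random.default_rng(seed)
    years = np.arange(1991, 1991 + n)
    return pd.DataFrame(
        {
            "year": years,
            "maize_JU": 20000 + 1500 * np.arange(n) + rng.normal(0, 800, n),
            "grassland_JU": 150000 - 600 * np.arange(n) + rng.normal(0, 2000, n),
            "harvest_rate": np.clip(0.02 + 0.002 * np.arange(n) + rng.normal(0, 0.004, n), 0, 1),
        }
    ).set_index("year", drop=False)


class TestDriverModel:
    def test_recovers_known_coefficient(self):
        cov = _cov()
        rng = np.random.default_rng(2)
        y = pd.Series(
            0.3 * scale_covariate(cov["maize_JU"]) + rng.normal(0, 0.01, 25),
            index=cov.index,
            name="resp",
        )
        fit = fit_driver_model(y, cov, ["maize_JU"])
        assert fit.params.loc["maize_JU", "estimate"] == pytest.approx(0.3, abs=0.05)
        assert fit.params.loc["maize_JU", "p"] < 0.05

    def test_exact_linear_interpolation(self):
        cov = _cov()
        y = pd.Series(
            0.1 + 0.2 * scale_covariate(cov["maize_JU"]), index=cov.index, name="resp"
        )
        fit = fit_driver_model(y, cov, ["maize_JU"], include_quadratic=False)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.params.loc["maize_JU", "estimate"] == pytest.approx(0.2, abs=1e-10)

    def test_unit_invariance(self):
        cov = _cov()
        rng = np.random.default_rng(3)
        y = pd.Series(
            0.3 * scale_covariate(cov["maize_JU"]) + rng.normal(0, 0.01, 25),
            index=cov.index,
            name="resp",
        )
        cov2 = cov.copy()
        cov2["maize_JU"] = cov2["maize_JU"] * 2.47 + 1000  # different units
        a = fit_driver_model(y, cov, ["maize_JU"]).params.loc["maize_JU", "estimate"]
        b = fit_driver_model(y, cov2, ["maize_JU"]).params.loc["maize_JU", "estimate"]
        assert a == pytest.approx(b, abs=1e-10)

    def test_missing_years_dropped_and_logged(self):
        cov = _cov()
        cov.loc[2012, "maize_JU"] = np.nan
        rng = np.random.default_rng(4)
        y = pd.Series(rng.uniform(0, 1, 25), index=cov.index, name="resp")
        fit = fit_driver_model(y, cov, ["maize_JU", "grassland_JU"])
        assert fit.dropped_years == [2012]
        assert fit.n_years == 24

    def test_year_range_restriction(self):
        cov = _cov()
        rng = np.random.default_rng(5)
        y = pd.Series(rng.uniform(0, 1, 25), index=cov.index, name="resp")
        fit = fit_driver_model(y, cov, ["maize_JU"], year_range=(1991, 2006))
        assert fit.n_years == 16
        assert max(fit.years_used) == 2006

    def test_collinear_covariates_named(self):
        cov = _cov()
        cov["maize_copy"] = cov["maize_JU"]
        y = pd.Series(np.linspace(0, 1, 25), index=cov.index, name="resp")
        with pytest.raises(ValueError, match="collinear"):
            fit_driver_model(y, cov, ["maize_JU", "maize_copy"])

    def test_quadratic_screen_reported(self):
        cov = _cov()
        x = scale_covariate(cov["maize_JU"])
        rng = np.random.default_rng(6)
        y = pd.Series(0.5 * scale_covariate(x**2) + rng.normal(0, 0.01, 25),
                      index=cov.index, name="resp")
        fit = fit_driver_model(y, cov, ["maize_JU"])
        assert "maize_JU^2" in set(fit.quadratic["covariate"])
        # a real quadratic signal is retained in the final model
        assert "maize_JU^2" in fit.params.index
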