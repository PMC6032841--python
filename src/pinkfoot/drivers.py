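"""Environmental-driver models: harvest, winter temperature and land use.

Annual proportions of birds *using* a region (summed over the four
strategies containing it; "staying in Jutland" means the Jutland-only
strategy) are regressed on scaled covariates with ordinary least squares.
Covariates are centered and range-scaled — x' = (x − mean) / (range/2) —
so that estimates are comparable across covariates measured in different
units.  Land-use models include all crop covariates of a region jointly;
harvest and temperature are single-covariate models.  Quadratic terms are
tested and dropped from the final model when not significant at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import Region, STRATEGIES
from .trends import ProportionSeries

__all__ = [
    "DriverFit",
    "proportion_using_region",
    "proportion_staying",
    "scale_covariate",
    "downscale_land_use",
    "fit_driver_model",
    "REGION_CROPS",
]

#: Food crops tracked per region (potatoes are a Flanders-only crop).
REGION_CROPS = {
    "JU": ("spring_cereal", "winter_cereal", "maize", "grassland"),
    "FR": ("spring_cereal", "winter_cereal", "maize", "grassland"),
    "FL": ("spring_cereal", "winter_cereal", "maize", "grassland", "potatoes"),
}


def proportion_using_region(series: ProportionSeries, region: Region) -> pd.Series:
    """Per-year proportion of birds whose strategy includes ``region``
    (the sum over the four strategies containing it)."""
    region = Region(region)
    mask = np.array([region in s.regions for s in STRATEGIES])
    vals = series.proportions[:, mask].sum(axis=1)
    return pd.Series(vals, index=series.years.astype(int), name=f"using_{region.name}")


def proportion_staying(series: ProportionSeries, region: Region = Region.JU) -> pd.Series:
    """Per-year proportion using only ``region`` (e.g. staying in Jutland
    the entire winter)."""
    region = Region(region)
    mask = np.array([s.regions == frozenset({region}) for s in STRATEGIES])
    vals = series.proportions[:, mask].sum(axis=1)
    return pd.Series(vals, index=series.years.astype(int), name=f"staying_{region.name}")


def scale_covariate(x) -> np.ndarray:
    """Center to mean zero and scale by half the range: the result has
    mean exactly 0 and max − min exactly 2 (endpoints are ±1 only when
    the series is symmetric about its mean)."""
    x = np.asarray(x, dtype=float)
    rng = x.max() - x.min()
    if rng <= 0:
        raise ValueError("cannot scale a constant covariate")
    return (x - x.mean()) / (rng / 2.0)


def downscale_land_use(crop_new: float, arable_old: float, arable_new: float) -> float:
    """Map a crop area reported on post-reform administrative units back
    onto the old-unit extent, in proportion to total arable land:
    crop_new × arable_old / arable_new."""
    if arable_old <= 0 or arable_new <= 0:
        raise ValueError("arable areas must be positive")
    if crop_new < 0:
        raise ValueError("crop area must be nonnegative")
    return crop_new * (arable_old / arable_new)


@dataclass
class DriverFit:
    """OLS fit of a region-use proportion on scaled covariates."""

    response: str
    params: pd.DataFrame  # index covariate; estimate, se, p
    quadratic: pd.DataFrame  # quadratic-term screen: estimate, se, p per covariate
    n_years: int
    r_squared: float
    f_stat: float
    f_p: float
    years_used: list
    dropped_years: list


def _ols(y: np.ndarray, X: np.ndarray, names: list) -> tuple[pd.DataFrame, object]:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    res = model.fit()
    tab = pd.DataFrame(
        {
            "estimate": res.params[1:],
            "se": res.bse[1:],
            "p": res.pvalues[1:],
        },
        index=names,
    )
    return tab, res


def fit_driver_model(
    response: pd.Series,
    covariates: pd.DataFrame,
    cols: list,
    year_range: tuple | None = None,
    include_quadratic: bool = True,
    alpha: float = 0.05,
) -> DriverFit:
    """Regress a yearly proportion on the scaled covariate columns.

    Rows are matched on year; years with any missing covariate are dropped
    listwise (and reported).  Quadratic effects (squares of the scaled
    covariates, re-scaled by the same rule) are screened one at a time
    alongside the linear terms; any significant at ``alpha`` is retained
    in the final model, otherwise the final model is linear-only.
    """
    cols = list(cols)
    df = pd.DataFrame({"__y": response}).join(covariates[cols], how="inner")
    if year_range is not None:
        df = df[(df.index >= year_range[0]) & (df.index <= year_range[1])]
    complete = df.dropna()
    dropped = sorted(set(df.index) - set(complete.index))
    if len(complete) < len(cols) + 2:
        raise ValueError(
            f"too few complete years ({len(complete)}) for {len(cols)} covariates"
        )
    y = complete["__y"].to_numpy(dtype=float)
    Xs = np.column_stack([scale_covariate(complete[c]) for c in cols])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xs])) < len(cols) + 1:
        corr = np.corrcoef(Xs, rowvar=False)
        pairs = [
            (cols[i], cols[j])
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear covariates: {pairs}")

    linear_tab, lin_res = _ols(y, Xs, cols)

    quad_rows = []
    keep_quad = []
    if include_quadratic and len(complete) < len(cols) + 4:
        import warnings

        warnings.warn(
            "too few years to screen quadratic terms; fitting linear effects only"
        )
        include_quadratic = False
    if include_quadratic:
        for i, c in enumerate(cols):
            q = scale_covariate(Xs[:, i] ** 2)
            tab, _ = _ols(y, np.column_stack([Xs, q]), cols + [f"{c}^2"])
            row = tab.loc[f"{c}^2"]
            quad_rows.append(
                {"covariate": f"{c}^2", "estimate": row["estimate"], "se": row["se"], "p": row["p"]}
            )
            if row["p"] < alpha:
                keep_quad.append(i)
    quad_tab = pd.DataFrame(quad_rows, columns=["covariate", "estimate", "se", "p"])

    if keep_quad:
        X_final = np.column_stack(
            [Xs] + [scale_covariate(Xs[:, i] ** 2) for i in keep_quad]
        )
        names = cols + [f"{cols[i]}^2" for i in keep_quad]
        params, res = _ols(y, X_final, names)
    else:
        params, res = linear_tab, lin_res

    return DriverFit(
        response=str(response.name),
        params=params,
        quadratic=quad_tab,
        n_years=len(complete),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
        years_used=[int(v) for v in complete.index],
        dropped_years=[int(v) for v in dropped],
    )


def region_landuse_columns(region: str) -> list:
    return [f"{crop}_{region}" for crop in REGION_CROPS[region]]
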