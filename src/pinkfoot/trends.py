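"""Annual strategy proportions and segmented (piecewise-linear) trends.

Each strategy's annual share of the marked population is modelled as a
continuous piecewise-linear function of year.  Breakpoints are estimated by
exhaustive grid search (coarse one-year grid, then 0.1-year local
refinement), the number of breakpoints is chosen by BIC, a change in slope
is tested with the Davies bound (the breakpoint is a nuisance parameter
that vanishes under the null), and breakpoint confidence intervals come
from a residual bootstrap.  Pooled breakpoints across strategies are
clustered into study periods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import STRATEGIES

__all__ = [
    "ProportionSeries",
    "PiecewiseFit",
    "annual_proportions",
    "fit_piecewise",
    "davies_test",
    "derive_periods",
]


@dataclass
class ProportionSeries:
    """Per-year strategy shares among birds with an assigned strategy."""

    years: np.ndarray  # (T,)
    proportions: np.ndarray  # (T, 7) in STRATEGIES order; rows sum to 1
    n: np.ndarray  # (T,) sample sizes

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, year in enumerate(self.years):
            for j, s in enumerate(STRATEGIES):
                rows.append(
                    {
                        "year": int(year),
                        "strategy": s.label,
                        "proportion": float(self.proportions[i, j]),
                        "n": int(self.n[i]),
                    }
                )
        return pd.DataFrame(rows)

    def series(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        j = [s.label for s in STRATEGIES].index(label)
        return self.years.astype(float), self.proportions[:, j]


def annual_proportions(table) -> ProportionSeries:
    """Tally the strategy table into per-year proportions.

    Seasons with zero assigned birds are omitted (with a warning when they
    fall inside the observed span).
    """
    if not table:
        raise ValueError("empty strategy table")
    counts: dict[int, np.ndarray] = {}
    index = {s: j for j, s in enumerate(STRATEGIES)}
    for (bird_id, year), strategy in table.items():
        counts.setdefault(year, np.zeros(len(STRATEGIES)))[index[strategy]] += 1
    years = np.array(sorted(counts))
    full_span = np.arange(years.min(), years.max() + 1)
    missing = set(full_span) - set(years.tolist())
    if missing:
        warnings.warn(f"seasons with no assigned birds omitted: {sorted(missing)}")
    mat = np.vstack([counts[y] for y in years])
    n = mat.sum(axis=1)
    return ProportionSeries(years=years, proportions=mat / n[:, None], n=n.astype(int))


@dataclass
class PiecewiseFit:
    """Continuous piecewise-linear least-squares fit."""

    breakpoints: list
    breakpoint_cis: list  # [(lo, hi)] per breakpoint (95% bootstrap)
    coef: np.ndarray  # intercept, base slope, slope changes at breakpoints
    segment_slopes: list
    residual_sd: float
    davies_p: float
    n_breakpoints: int
    bic: dict
    x_range: tuple

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _basis(x, self.breakpoints) @ self.coef


def _basis(x: np.ndarray, breaks) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.clip(x - b, 0.0, None))
    return np.column_stack(cols)


def _rss(x, y, breaks):
    B = _basis(x, breaks)
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return float(resid @ resid), coef


def _valid(x, breaks, min_seg):
    bounds = [-np.inf, *breaks, np.inf]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if np.sum((x > lo) & (x <= hi)) < min_seg and not np.isinf(hi):
            return False
        if np.isinf(hi) and np.sum(x > lo) < min_seg:
            return False
    return True


def _search_breaks(x, y, k, min_seg, coarse_step=1.0, fine_step=0.1, around=None):
    """Best k-break fit: exhaustive coarse grid then coordinate-wise
    refinement at ``fine_step`` resolution.  ``around`` restricts the
    coarse stage to neighbourhoods of given breakpoints (bootstrap use)."""
    lo, hi = float(x.min()), float(x.max())
    if around is None:
        cand = np.arange(lo + coarse_step, hi - coarse_step / 2, coarse_step)
        combos = itertools.combinations(cand, k)
    else:
        grids = [
            np.arange(max(lo + fine_step, b - 2.0), min(hi - fine_step, b + 2.0) + 1e-9, 5 * fine_step)
            for b in around
        ]
        combos = itertools.product(*grids)
    best = (np.inf, None, None)
    for breaks in combos:
        breaks = list(breaks)
        if any(b2 - b1 < coarse_step / 2 for b1, b2 in zip(breaks, breaks[1:])):
            continue
        if not _valid(x, breaks, min_seg):
            continue
        rss, coef = _rss(x, y, breaks)
        if rss < best[0]:
            best = (rss, breaks, coef)
    if best[1] is None:
        return None
    # coordinate-wise refinement
    rss, breaks, coef = best
    for _ in range(3):
        improved = False
        for i in range(k):
            grid = np.arange(breaks[i] - 1.0, breaks[i] + 1.0 + 1e-9, fine_step)
            for b in grid:
                trial = sorted(breaks[:i] + [float(b)] + breaks[i + 1:])
                if any(t2 - t1 < fine_step for t1, t2 in zip(trial, trial[1:])):
                    continue
                if not (lo < trial[0] and trial[-1] < hi):
                    continue
                if not _valid(x, trial, min_seg):
                    continue
                r, c = _rss(x, y, trial)
                if r < rss - 1e-15:
                    rss, breaks, coef, improved = r, trial, c, True
        if not improved:
            break
    return rss, breaks, coef


def fit_piecewise(
    x,
    y,
    max_breaks: int = 3,
    n_boot: int = 500,
    seed: int = 0,
    min_seg: int = 2,
) -> PiecewiseFit:
    """Fit a continuous piecewise-linear trend with 0..max_breaks breaks.

    The number of breakpoints is selected by BIC (each break costs two
    parameters: a slope change and a location).  95% breakpoint CIs come
    from a residual bootstrap (re-estimating breakpoints locally in each
    replicate).  With ``max_breaks=0`` this reduces exactly to ordinary
    least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 2 * (max_breaks + 1) + 1:
        raise ValueError(
            f"need at least {2 * (max_breaks + 1) + 1} points for max_breaks={max_breaks}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    order = np.argsort(x)
    x, y = x[order], y[order]

    rss_floor = n * 1e-14 * max(float(np.var(y)), 1e-12)
    fits = {}
    rss0, coef0 = _rss(x, y, [])
    fits[0] = (rss0, [], coef0)
    for k in range(1, max_breaks + 1):
        out = _search_breaks(x, y, k, min_seg)
        if out is not None:
            fits[k] = out

    bic = {}
    for k, (rss, breaks, coef) in fits.items():
        bic[k] = n * np.log(max(rss, rss_floor) / n) + (2 + 2 * k) * np.log(n)
    k_best = min(bic, key=lambda k: (round(bic[k], 10), k))
    rss, breaks, coef = fits[k_best]

    dof = max(n - (2 + 2 * k_best), 1)
    resid_sd = float(np.sqrt(max(rss, 0.0) / dof))
    p_davies = davies_test(x, y) if n >= 8 else np.nan

    cis = []
    if k_best > 0 and n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = _basis(x, breaks) @ coef
        resid = y - fitted
        resid = resid - resid.mean()
        samples: list[list[float]] = [[] for _ in range(k_best)]
        for _ in range(n_boot):
            yb = fitted + rng.choice(resid, size=n, replace=True)
            out = _search_breaks(x, yb, k_best, min_seg, around=breaks)
            if out is None:
                continue
            for i, b in enumerate(out[1]):
                samples[i].append(b)
        for i in range(k_best):
            if samples[i]:
                lo_q, hi_q = np.percentile(samples[i], [2.5, 97.5])
                cis.append((float(lo_q), float(hi_q)))
            else:
                cis.append((np.nan, np.nan))

    slopes = [float(coef[1])]
    for j in range(k_best):
        slopes.append(slopes[-1] + float(coef[2 + j]))
    return PiecewiseFit(
        breakpoints=[float(b) for b in breaks],
        breakpoint_cis=cis,
        coef=coef,
        segment_slopes=slopes,
        residual_sd=resid_sd,
        davies_p=float(p_davies) if p_davies == p_davies else np.nan,
        n_breakpoints=k_best,
        bic={k: float(v) for k, v in bic.items()},
        x_range=(float(x.min()), float(x.max())),
    )


def davies_test(x, y, k_candidates: int = 10) -> float:
    """Test for a change in slope at an unknown breakpoint.

    Evaluates the Wald statistic for adding a hinge term (x − ψ)₊ to the
    straight-line model at ``k_candidates`` evenly spaced interior
    candidate breakpoints, and bounds the p-value of the supremum using
    Davies' correction: p ≤ p_naive(M) + V·exp(−M²/2)/√(8π), where V is
    the total variation of the statistic path.  The naive tail uses the t
    distribution appropriate to the per-candidate fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("davies_test needs at least 8 points")
    lo, hi = np.sort(x)[1], np.sort(x)[-2]
    if k_candidates > n - 4:
        warnings.warn(
            f"reducing candidate breakpoints from {k_candidates} to {n - 4}"
        )
        k_candidates = n - 4
    psis = np.linspace(lo, hi, k_candidates + 2)[1:-1]
    dof = n - 3
    scale = float(np.max(np.abs(y - y.mean()), initial=0.0))
    if scale <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return 1.0  # constant response: no slope anywhere
    ts = np.zeros(len(psis))
    for i, psi in enumerate(psis):
        B = np.column_stack([np.ones(n), x, np.clip(x - psi, 0.0, None)])
        coef, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
        if rank < 3:
            continue
        resid = y - B @ coef
        sigma2 = float(resid @ resid) / dof
        try:
            cov = np.linalg.inv(B.T @ B)
        except np.linalg.LinAlgError:
            continue
        se = np.sqrt(max(sigma2 * cov[2, 2], 0.0))
        if se <= 1e-300:
            ts[i] = 0.0 if abs(coef[2]) <= 1e-300 else np.inf
        else:
            ts[i] = coef[2] / se
    M = float(np.max(np.abs(ts)))
    if M == 0.0:
        return 1.0
    if not np.isfinite(M):
        return np.finfo(float).tiny
    V = float(np.sum(np.abs(np.diff(ts))))
    # finite-sample kernel: for t-distributed statistics the upcrossing
    # term uses (1 + M^2/nu)^(-(nu-1)/2) in place of the normal exp(-M^2/2)
    kernel = (1.0 + M * M / dof) ** (-(dof - 1) / 2.0)
    p_one = stats.t.sf(M, dof) + V * kernel / np.sqrt(8.0 * np.pi)
    return float(min(1.0, 2.0 * p_one))


def derive_periods(fits, span: tuple | None = None, gap: float = 2.0) -> list:
    """Cluster pooled breakpoints into consecutive study periods.

    All breakpoints from the per-strategy fits are pooled, 1-D clustered
    with a gap threshold (default 2 years), cluster centers are rounded
    down to season boundaries, and the study span is cut after each
    boundary year.  Returns inclusive (first_year, last_year) intervals.
    """
    fits = list(fits)
    if span is None:
        lo = min(f.x_range[0] for f in fits)
        hi = max(f.x_range[1] for f in fits)
        span = (int(round(lo)), int(round(hi)))
    points = sorted(b for f in fits for b in f.breakpoints)
    if not points:
        return [span]
    clusters = [[points[0]]]
    for b in points[1:]:
        if b - clusters[-1][-1] <= gap:
            clusters[-1].append(b)
        else:
            clusters.append([b])
    cuts = sorted({int(np.floor(np.mean(c))) for c in clusters})
    cuts = [c for c in cuts if span[0] <= c < span[1]]
    periods = []
    start = span[0]
    for c in cuts:
        periods.append((start, c))
        start = c + 1
    periods.append((start, span[1]))
    return periods
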