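"""Random-intercept logistic regression (binomial GLMM, logit link).

Fits models of the form

    logit P(change) = x'beta + u_bird + u_year,
    u_bird ~ N(0, sd_bird^2),  u_year ~ N(0, sd_year^2)  (crossed),

by maximizing the Laplace-approximated marginal likelihood.  The joint
mode of the random effects is found by Newton iterations; the (bird +
year) Hessian has an arrow structure — the bird block is diagonal and the
year block is small — so each Newton step and the log-determinant use a
Schur complement on the year block, keeping cost linear in the number of
birds.  For models with a single grouping factor, adaptive Gauss–Hermite
quadrature (``nagq`` > 1) refines the per-group integrals around the same
Laplace mode.

Wald inference throughout: standard errors of the fixed effects come from
the numerical Hessian of the Laplace log-likelihood at the optimum with
the variance parameters held at their estimates, matching the usual
mixed-model convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic_mixed",
    "fit_glmm",
]

_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-4), np.log(20.0)


class SeparationError(RuntimeError):
    """Raised when the likelihood is unbounded (separated data)."""


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the optimizer message."""


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification over a change-event data frame.

    ``fixed`` lists covariate columns: numeric columns enter linearly
    (continuous covariates are centered internally and reported on their
    original scale); string columns are treatment-coded against their
    first sorted level.  ``random`` is a subset of column names used as
    crossed random-intercept factors.
    """

    response: str = "changed"
    fixed: tuple = ()
    random: tuple = ("bird_id",)

    def __post_init__(self):
        if len(self.random) > 2:
            raise ValueError("at most two crossed random factors supported")


@dataclass
class GlmmFit:
    """Fitted mixed logistic model."""

    params: pd.DataFrame  # index: term; columns: estimate, se, z, p
    vcov: pd.DataFrame
    variances: dict  # grouping factor -> random-intercept variance
    loglik: float
    n_obs: int
    n_groups: dict
    spec: GlmmSpec
    predictions: pd.DataFrame | None = None
    offsets: dict = field(default_factory=dict)  # e.g. centering constants

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def predict_prob(self, x_row: np.ndarray) -> tuple[float, float, float]:
        """Population-level probability at design row ``x_row`` with a 95%
        Wald CI computed on the logit scale and back-transformed."""
        beta = self.params["estimate"].to_numpy()
        eta = float(x_row @ beta)
        se = float(np.sqrt(x_row @ self.vcov.to_numpy() @ x_row))
        lo, hi = eta - 1.959963984540054 * se, eta + 1.959963984540054 * se
        return float(special.expit(eta)), float(special.expit(lo)), float(special.expit(hi))

    def contrast(self, terms_a: dict, terms_b: dict) -> dict:
        """Wald test of a difference of two linear combinations of terms."""
        c = np.zeros(len(self.params))
        idx = {t: i for i, t in enumerate(self.params.index)}
        for t, w in terms_a.items():
            c[idx[t]] += w
        for t, w in terms_b.items():
            c[idx[t]] -= w
        est = float(c @ self.params["estimate"].to_numpy())
        se = float(np.sqrt(c @ self.vcov.to_numpy() @ c))
        z = est / se if se > 0 else np.inf
        return {"estimate": est, "se": se, "z": z, "p": 2 * stats.norm.sf(abs(z))}


# ---------------------------------------------------------------------------
# numerical core


def _accum(idx: np.ndarray, values: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros(size)
    np.add.at(out, idx, values)
    return out


def _joint_parts(y, X, beta, gb, gy, ub, uy):
    eta = X @ beta
    if gb is not None:
        eta = eta + ub[gb]
    if gy is not None:
        eta = eta + uy[gy]
    mu = special.expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return eta, mu, ll


def _inner_mode(y, X, beta, gb, nb, gy, ny, sb2, sy2, ub, uy, tol=1e-10, max_iter=100):
    """Newton maximization of the joint log-density over random effects.

    Returns the mode, the log-determinant of the negative Hessian there,
    and the penalized log-likelihood at the mode.
    """
    for _ in range(max_iter):
        eta, mu, ll = _joint_parts(y, X, beta, gb, gy, ub, uy)
        w = mu * (1.0 - mu) + 1e-12
        resid = y - mu
        if gb is not None and gy is not None:
            grad_b = _accum(gb, resid, nb) - ub / sb2
            grad_y = _accum(gy, resid, ny) - uy / sy2
            A = _accum(gb, w, nb) + 1.0 / sb2
            B = _accum(gy, w, ny) + 1.0 / sy2
            C = np.zeros((nb, ny))
            np.add.at(C, (gb, gy), w)
            # Schur complement on the (small) year block
            CA = C / A[:, None]
            S = np.diag(B) - CA.T @ C
            rhs_y = grad_y - CA.T @ grad_b
            dy = np.linalg.solve(S, rhs_y)
            db = (grad_b - C @ dy) / A
            step_b, step_y = db, dy
            gmax = max(np.abs(grad_b).max(), np.abs(grad_y).max())
        elif gb is not None:
            grad_b = _accum(gb, resid, nb) - ub / sb2
            A = _accum(gb, w, nb) + 1.0 / sb2
            step_b, step_y = grad_b / A, None
            gmax = np.abs(grad_b).max()
        else:
            grad_y = _accum(gy, resid, ny) - uy / sy2
            B = _accum(gy, w, ny) + 1.0 / sy2
            step_b, step_y = None, grad_y / B
            gmax = np.abs(grad_y).max()

        pen = 0.0
        if gb is not None:
            pen += 0.5 * float(ub @ ub) / sb2
        if gy is not None:
            pen += 0.5 * float(uy @ uy) / sy2
        obj = ll - pen

        # damped Newton: halve until the objective does not decrease
        scale = 1.0
        for _ls in range(30):
            ub_new = ub + scale * step_b if gb is not None else ub
            uy_new = uy + scale * step_y if gy is not None else uy
            _, _, ll_new = _joint_parts(y, X, beta, gb, gy, ub_new, uy_new)
            pen_new = 0.0
            if gb is not None:
                pen_new += 0.5 * float(ub_new @ ub_new) / sb2
            if gy is not None:
                pen_new += 0.5 * float(uy_new @ uy_new) / sy2
            if ll_new - pen_new >= obj - 1e-12:
                break
            scale *= 0.5
        ub, uy = ub_new, uy_new
        if gmax < tol or scale * gmax < tol:
            break

    # log-determinant of the negative joint Hessian at the mode
    eta, mu, ll = _joint_parts(y, X, beta, gb, gy, ub, uy)
    w = mu * (1.0 - mu) + 1e-12
    if gb is not None and gy is not None:
        A = _accum(gb, w, nb) + 1.0 / sb2
        B = _accum(gy, w, ny) + 1.0 / sy2
        C = np.zeros((nb, ny))
        np.add.at(C, (gb, gy), w)
        S = np.diag(B) - (C / A[:, None]).T @ C
        sign, logdet_s = np.linalg.slogdet(S)
        logdet = float(np.sum(np.log(A)) + logdet_s)
    elif gb is not None:
        A = _accum(gb, w, nb) + 1.0 / sb2
        logdet = float(np.sum(np.log(A)))
    else:
        B = _accum(gy, w, ny) + 1.0 / sy2
        logdet = float(np.sum(np.log(B)))

    pen = 0.0
    if gb is not None:
        pen += 0.5 * float(ub @ ub) / sb2
    if gy is not None:
        pen += 0.5 * float(uy @ uy) / sy2
    return ub, uy, logdet, ll - pen


def _laplace_loglik(theta, y, X, gb, nb, gy, ny, state):
    p = X.shape[1]
    beta = theta[:p]
    k = p
    sb2 = sy2 = None
    if gb is not None:
        sb2 = float(np.exp(2.0 * theta[k])); k += 1
    if gy is not None:
        sy2 = float(np.exp(2.0 * theta[k])); k += 1
    ub = state.get("ub") if gb is not None else None
    uy = state.get("uy") if gy is not None else None
    if gb is not None and ub is None:
        ub = np.zeros(nb)
    if gy is not None and uy is None:
        uy = np.zeros(ny)
    ub, uy, logdet, pen_ll = _inner_mode(y, X, beta, gb, nb, gy, ny, sb2, sy2, ub, uy)
    state["ub"], state["uy"] = ub, uy
    ll = pen_ll - 0.5 * logdet
    if gb is not None:
        ll -= 0.5 * nb * np.log(sb2)
    if gy is not None:
        ll -= 0.5 * ny * np.log(sy2)
    return ll


def _agq_loglik(theta, y, X, gb, nb, nagq):
    """Adaptive Gauss–Hermite marginal log-likelihood, single factor."""
    p = X.shape[1]
    beta, sb2 = theta[:p], float(np.exp(2.0 * theta[p]))
    ub = np.zeros(nb)
    ub, _, _, _ = _inner_mode(y, X, beta, gb, nb, None, 0, sb2, None, ub, None)
    eta0 = X @ beta
    mu = special.expit(eta0 + ub[gb])
    w = mu * (1.0 - mu) + 1e-12
    A = _accum(gb, w, nb) + 1.0 / sb2  # per-group curvature at the mode
    shat = 1.0 / np.sqrt(A)
    nodes, wts = np.polynomial.hermite_e.hermegauss(nagq)  # probabilists'
    logint = np.full((nb, nagq), -np.inf)
    for k, (t, wk) in enumerate(zip(nodes, wts)):
        u = ub + shat * t
        eta = eta0 + u[gb]
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        ll_g = _accum(gb, ll_obs, nb)
        ll_g += -0.5 * u * u / sb2 - 0.5 * np.log(2 * np.pi * sb2)
        # back out the probabilists' weight kernel and add log integration wt
        logint[:, k] = np.log(wk) + ll_g + 0.5 * t * t + np.log(shat)
    total = special.logsumexp(logint, axis=1)
    return float(np.sum(total))


def _numeric_hessian(f, x0, h=1e-4):
    n = len(x0)
    H = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


def _irls_logistic(y, X, max_iter=25):
    """Plain logistic starting values (IRLS)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1 - mu) + 1e-10
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = np.clip(beta_new, -30, 30)
    return beta


def fit_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray,
    term_names: list,
    groups: dict,
    nagq: int = 1,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GlmmFit:
    """Fit the mixed logistic model on an explicit design.

    ``groups`` maps factor name → integer label array (codes 0..n_groups-1)
    with at most two factors.  ``nagq`` > 1 switches to adaptive
    Gauss–Hermite quadrature (single factor only).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise SeparationError("response is constant: model is degenerate")
    factor_names = list(groups)
    if len(factor_names) > 2:
        raise ValueError("at most two crossed random factors supported")
    codes = {}
    sizes = {}
    for name, lab in groups.items():
        lab = np.asarray(lab)
        _, code = np.unique(lab, return_inverse=True)
        codes[name] = code
        sizes[name] = int(code.max()) + 1
        if sizes[name] < 2:
            warnings.warn(f"random factor {name!r} has a single level; its "
                          "variance is not identifiable", RuntimeWarning)
    gb = codes[factor_names[0]] if len(factor_names) >= 1 else None
    nb = sizes[factor_names[0]] if gb is not None else 0
    gy = codes[factor_names[1]] if len(factor_names) == 2 else None
    ny = sizes[factor_names[1]] if gy is not None else 0
    if nagq > 1 and gy is not None:
        raise ValueError("adaptive quadrature supports a single grouping factor")

    p = X.shape[1]
    beta0 = _irls_logistic(y, X)
    theta0 = np.concatenate([beta0, np.full(len(factor_names), np.log(0.3))])
    state: dict = {}

    if nagq > 1:
        def nll(theta):
            return -_agq_loglik(theta, y, X, gb, nb, nagq)
    else:
        def nll(theta):
            return -_laplace_loglik(theta, y, X, gb, nb, gy, ny, state)

    bounds = [(None, None)] * p + [(_LOG_SD_MIN, _LOG_SD_MAX)] * len(factor_names)
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-6},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(f"GLMM optimizer failed: {res.message}")
    theta = res.x
    beta = theta[:p]
    big = np.abs(beta[1:] if term_names[0] == "(Intercept)" else beta) > 15
    if big.any():
        offenders = [t for t, b in zip(term_names, np.abs(beta) > 15) if b]
        raise SeparationError(
            "apparent complete separation: unbounded coefficient(s) for "
            + ", ".join(offenders)
        )

    variances = {}
    for i, name in enumerate(factor_names):
        sd = float(np.exp(theta[p + i]))
        variances[name] = 0.0 if sd <= 2e-4 else sd * sd

    def nll_beta(b):
        th = theta.copy()
        th[:p] = b
        return nll(th)

    Hb = _numeric_hessian(nll_beta, beta.copy())
    try:
        vcov = np.linalg.inv(Hb)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(Hb)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    z = np.divide(beta, se, out=np.full(p, np.inf), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": pvals}, index=term_names
    )
    return GlmmFit(
        params=params,
        vcov=pd.DataFrame(vcov, index=term_names, columns=term_names),
        variances=variances,
        loglik=float(-res.fun),
        n_obs=len(y),
        n_groups=sizes,
        spec=GlmmSpec(fixed=tuple(term_names), random=tuple(factor_names)),
    )


# ---------------------------------------------------------------------------
# data-frame front end


def build_design(df: pd.DataFrame, fixed: tuple) -> tuple[np.ndarray, list, dict]:
    """Design matrix with intercept; numeric columns centered, string
    columns treatment-coded against the first sorted level.  Returns
    (X, term names, centering offsets)."""
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    offsets: dict[str, float] = {}
    for term in fixed:
        col = df[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            center = float(col.mean())
            offsets[term] = center
            cols.append(col.to_numpy(dtype=float) - center)
            names.append(term)
        elif pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names, offsets


def fit_glmm(data, spec: GlmmSpec, nagq: int = 1, tol: float = 1e-8) -> GlmmFit:
    """Fit a :class:`GlmmSpec` on change-event data.

    ``data`` is a data frame (or a list of change events, converted via
    their frame representation).  Continuous fixed effects are centered for
    conditioning; the reported slope is on the original per-unit scale and
    the centering constants are stored in ``fit.offsets``.
    """
    if not isinstance(data, pd.DataFrame):
        from .assign import events_to_frame

        data = events_to_frame(data)
    if len(data) == 0:
        raise ValueError("no events to fit")
    y = data[spec.response].astype(float).to_numpy()
    X, names, offsets = build_design(data, spec.fixed)
    groups = {g: data[g].to_numpy() for g in spec.random}
    fit = fit_logistic_mixed(y, X, names, groups, nagq=nagq, tol=tol)
    fit.offsets = offsets
    fit.spec = GlmmSpec(response=spec.response, fixed=tuple(names), random=spec.random)
    return fit
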