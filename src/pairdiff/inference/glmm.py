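"""Mixed-effects logistic regression.

Maximum-likelihood fits of a Bernoulli GLMM with Gaussian per-group
random effects.  With a random intercept only, the marginal likelihood
is integrated by adaptive Gauss-Hermite quadrature (vectorized across
groups); with random slopes it falls back to a per-group Laplace
approximation.  Nested models are compared with likelihood ratio tests.

Fixed terms are structured column references, not formula strings:
numeric columns enter as-is, string/categorical columns are dummy-coded
against their first (sorted) level, and ``"a:b"`` denotes the product
of two numeric terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, log_expit

__all__ = ["GlmmSpec", "GlmmFit", "SeparationError", "fit_mixed_logistic", "lrt"]


class SeparationError(RuntimeError):
    """Raised when the response is (quasi-)completely separated."""


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: binary response, fixed terms, grouping
    column, and which fixed terms also get per-group random slopes."""

    response: str
    fixed: tuple[str, ...]
    group: str = "subject"
    random_slopes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = [t for t in self.random_slopes if t not in self.fixed]
        if unknown:
            raise ValueError(f"random slopes must reference fixed terms: {unknown}")


@dataclass(frozen=True)
class GlmmFit:
    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    random_structure: str
    random_sd: pd.Series
    message: str = ""
    spec: GlmmSpec | None = field(default=None, repr=False)

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        est, se = self.params[term], self.se[term]
        return est - zcrit * se, est + zcrit * se

    def summary(self) -> pd.DataFrame:
        z = self.params / self.se
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def _term_columns(data: pd.DataFrame, term: str) -> tuple[list[str], np.ndarray]:
    """Expand one structured term into named design columns."""
    if ":" in term:
        left, right = term.split(":", 1)
        lnames, lcols = _term_columns(data, left)
        rnames, rcols = _term_columns(data, right)
        if lcols.shape[1] != 1 or rcols.shape[1] != 1:
            raise ValueError(f"interaction {term!r} requires numeric terms")
        return [term], lcols * rcols
    col = data[term]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
        return [term], col.to_numpy(dtype=float)[:, None]
    levels = sorted(pd.unique(col.astype(str)))
    cols = [
        (f"{term}[{lvl}]", (col.astype(str) == lvl).to_numpy(dtype=float))
        for lvl in levels[1:]
    ]
    if not cols:
        raise ValueError(f"categorical term {term!r} has a single level")
    return [n for n, _ in cols], np.column_stack([c for _, c in cols])


def _build_design(data: pd.DataFrame, terms: Sequence[str], intercept: bool = True):
    names: list[str] = ["(Intercept)"] if intercept else []
    blocks: list[np.ndarray] = [np.ones((len(data), 1))] if intercept else []
    for term in terms:
        n, c = _term_columns(data, term)
        names.extend(n)
        blocks.append(c)
    return names, np.hstack(blocks) if blocks else np.empty((len(data), 0))


def _check_response(y: np.ndarray) -> None:
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all():
        raise ValueError("response must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("response has a single class; model is not identifiable")


def _plain_logit_start(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    """Fixed-effects-only start values; doubles as a separation guard."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"complete separation detected in fixed-effects logistic fit: {exc}"
            ) from exc
    if np.any(np.abs(res.params) > 30):
        big = [names[i] for i in np.flatnonzero(np.abs(res.params) > 30)]
        raise SeparationError(
            f"(quasi-)complete separation: diverging coefficients for {big}"
        )
    return np.asarray(res.params, dtype=float)


def _bernoulli_ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log p(y|eta) elementwise, numerically stable
    return y * log_expit(eta) + (1 - y) * log_expit(-eta)


def _nll_intercept(params, X, y, gidx, n_groups, gh_nodes, gh_weights, newton_iters=30):
    """Negative marginal log-likelihood, random intercept, adaptive GH."""
    beta, log_sd = params[:-1], params[-1]
    sd = np.exp(log_sd)
    base = X @ beta
    u = np.zeros(n_groups)
    for _ in range(newton_iters):
        eta = base + sd * u[gidx]
        p = expit(eta)
        grad = sd * np.bincount(gidx, weights=y - p, minlength=n_groups) - u
        hess = sd**2 * np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) + 1.0
        step = np.clip(grad / hess, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = base + sd * u[gidx]
    p = expit(eta)
    hess = sd**2 * np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) + 1.0
    s = 1.0 / np.sqrt(hess)  # adaptive scale per group

    # h(u) = sum_i loglik + log phi(u); integrate exp(h) over u by GH
    K = len(gh_nodes)
    hvals = np.empty((K, n_groups))
    for k, a in enumerate(gh_nodes):
        uk = u + np.sqrt(2.0) * s * a
        ll_obs = _bernoulli_ll(base + sd * uk[gidx], y)
        hvals[k] = (
            np.bincount(gidx, weights=ll_obs, minlength=n_groups)
            - 0.5 * uk**2
            - 0.5 * np.log(2 * np.pi)
            + a * a  # cancels the e^{-a^2} folded into GH weights
        )
    logw = np.log(gh_weights)[:, None] + np.log(np.sqrt(2.0) * s)[None, :] + hvals
    m = logw.max(axis=0)
    group_ll = m + np.log(np.exp(logw - m).sum(axis=0))
    return -group_ll.sum()


def _chol_from_params(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(theta[:q])
    if q > 1:
        L[np.tril_indices(q, -1)] = theta[q:]
    return L


def _nll_laplace(params, X, y, Z, groups, q, n_fixed, newton_iters=50):
    """Negative marginal log-likelihood, general q, per-group Laplace."""
    beta = params[:n_fixed]
    L = _chol_from_params(params[n_fixed:], q)
    base = X @ beta
    total = 0.0
    for idx in groups:
        Zi = Z[idx] @ L  # (n_i, q)
        yi = y[idx]
        bi = base[idx]
        u = np.zeros(q)
        obj_prev = -np.inf
        for _ in range(newton_iters):
            eta = bi + Zi @ u
            p = expit(eta)
            g = Zi.T @ (yi - p) - u
            W = p * (1 - p)
            H = Zi.T @ (Zi * W[:, None]) + np.eye(q)
            step = np.linalg.solve(H, g)
            u_new = u + step
            obj = _bernoulli_ll(bi + Zi @ u_new, yi).sum() - 0.5 * u_new @ u_new
            if obj < obj_prev:  # rare; damp
                u_new = u + 0.5 * step
                obj = _bernoulli_ll(bi + Zi @ u_new, yi).sum() - 0.5 * u_new @ u_new
            u, obj_prev = u_new, obj
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = bi + Zi @ u
        p = expit(eta)
        W = p * (1 - p)
        H = Zi.T @ (Zi * W[:, None]) + np.eye(q)
        sign, logdet = np.linalg.slogdet(H)
        total += (
            _bernoulli_ll(eta, yi).sum() - 0.5 * u @ u - 0.5 * logdet
        )
    return -total


def _numerical_hessian(fun, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            xi = np.array(x)
            pp = xi.copy(); pp[i] += eps; pp[j] += eps
            pm = xi.copy(); pm[i] += eps; pm[j] -= eps
            mp = xi.copy(); mp[i] -= eps; mp[j] += eps
            mm = xi.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (fun(pp) - fun(pm) - fun(mp) + fun(mm)) / (4 * eps**2)
    return H


def fit_mixed_logistic(
    data: pd.DataFrame,
    spec: GlmmSpec,
    n_quadrature: int = 11,
    compute_se: bool = True,
    _allow_fallback: bool = True,
) -> GlmmFit:
    """Fit the GLMM described by ``spec`` to ``data``.

    If the requested (maximal) random-slope structure fails to converge
    the model is refit with a random intercept only and the
    simplification is recorded in ``random_structure``.
    """
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 groups (subjects)")
    y = data[spec.response].to_numpy(dtype=float)
    _check_response(y)
    names, X = _build_design(data, spec.fixed)
    start_beta = _plain_logit_start(X, y, names)

    group_codes, _ = pd.factorize(data[spec.group], sort=True)
    n_groups = group_codes.max() + 1

    rs_names: list[str] = []
    Zblocks = [np.ones((len(data), 1))]
    for term in spec.random_slopes:
        tn, tc = _term_columns(data, term)
        rs_names.extend(tn)
        Zblocks.append(tc)
    Z = np.hstack(Zblocks)
    q = Z.shape[1]

    nodes, weights = hermgauss(n_quadrature)
    n_fixed = X.shape[1]

    if q == 1:
        def nll(p):
            return _nll_intercept(p, X, y, group_codes, n_groups, nodes, weights)
        n_var = 1
        structure = "random intercept"
    else:
        groups = [np.flatnonzero(group_codes == g) for g in range(n_groups)]

        def nll(p):
            return _nll_laplace(p, X, y, Z, groups, q, n_fixed)
        n_var = q + q * (q - 1) // 2
        structure = f"random intercept + slopes({', '.join(rs_names)})"

    x0 = np.concatenate([start_beta, np.full(q, np.log(0.5)), np.zeros(n_var - q)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 5e-3

    if not converged and q > 1 and _allow_fallback:
        fit = fit_mixed_logistic(
            data,
            GlmmSpec(spec.response, spec.fixed, spec.group, ()),
            n_quadrature=n_quadrature,
            compute_se=compute_se,
            _allow_fallback=False,
        )
        return GlmmFit(
            params=fit.params,
            se=fit.se,
            cov=fit.cov,
            loglik=fit.loglik,
            n_obs=fit.n_obs,
            n_params=fit.n_params,
            converged=fit.converged,
            random_structure="random intercept (fallback from maximal)",
            random_sd=fit.random_sd,
            message=f"maximal structure failed to converge: {res.message}",
            spec=spec,
        )

    est = res.x
    loglik = -float(res.fun)
    if compute_se:
        H = _numerical_hessian(nll, est)
        try:
            cov_all = np.linalg.inv(H)
            bad = np.diag(cov_all) <= 0
            se_all = np.sqrt(np.where(bad, np.nan, np.diag(cov_all)))
        except np.linalg.LinAlgError:
            cov_all = np.full((len(est), len(est)), np.nan)
            se_all = np.full(len(est), np.nan)
    else:
        cov_all = np.full((len(est), len(est)), np.nan)
        se_all = np.full(len(est), np.nan)

    params = pd.Series(est[:n_fixed], index=names)
    se = pd.Series(se_all[:n_fixed], index=names)
    cov = pd.DataFrame(cov_all[:n_fixed, :n_fixed], index=names, columns=names)
    sd_names = ["(Intercept)"] + rs_names
    random_sd = pd.Series(np.exp(est[n_fixed : n_fixed + q]), index=sd_names[:q])
    return GlmmFit(
        params=params,
        se=se,
        cov=cov,
        loglik=loglik,
        n_obs=len(y),
        n_params=n_fixed + n_var,
        converged=converged,
        random_structure=structure,
        random_sd=random_sd,
        message=str(res.message),
        spec=spec,
    )


def lrt(full: GlmmFit, nested: GlmmFit):
    """Likelihood ratio test of nested against full.

    chi2 = 2 (ll_full - ll_nested), df = parameter-count difference.
    """
    from .classical import TestResult

    if full.spec is not None and nested.spec is not None:
        if not set(nested.spec.fixed).issubset(set(full.spec.fixed)):
            raise ValueError("models are not nested (nested fixed terms not a subset)")
    if full.n_obs != nested.n_obs:
        raise ValueError("models must be fit to the same data")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than nested model")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return TestResult(name="likelihood ratio test", statistic=stat, df=float(df), p_value=p)
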