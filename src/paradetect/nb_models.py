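"""Negative-binomial GLM/GLMM and Gaussian LMM fitters.

The count models are NB2 with a log link: ``Var(Y) = mu + mu^2/k`` with the
dispersion (size) parameter ``k`` estimated by maximum likelihood on the
log scale, bounded to ``[1e-3, 1e6]``; hitting a bound is flagged, not an
error, because equidispersed or sparse pairs routinely push ``k`` to the
Poisson boundary.  The mixed variant integrates a single Gaussian random
intercept per group out of the likelihood by adaptive Gauss-Hermite
quadrature centred on the per-group Laplace mode (5 nodes by default).

Gaussian linear mixed models delegate to statsmodels MixedLM (REML), with
an OLS fallback when there is no usable grouping structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .errors import InvalidInputError, ModelFitError, RankDeficientError

K_MIN, K_MAX = 1e-3, 1e6
_LOG_K_BOUNDS = (math.log(K_MIN), math.log(K_MAX))
_SIGMA_MAX = 5.0
_ETA_CLIP = 30.0

#: convergence contract: relative log-likelihood tolerance and iteration cap
LL_RTOL = 1e-8
MAX_ITER = 500


@dataclass
class ModelFit:
    """Coefficient table plus likelihood summaries for one fitted model."""

    coefficients: dict
    standard_errors: dict
    z_values: dict
    p_values: dict
    log_likelihood: float
    aic: float
    dispersion_k: float
    n_obs: int
    converged: bool
    n_params: int
    random_intercept_sd: float | None = None
    dispersion_at_boundary: bool = False
    statistic: str = "z"  # "z" (normal reference) or "t" (residual df)
    df_resid: int | None = None
    method: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Flat (term, estimate, se, z, p) coefficient table."""
        return pd.DataFrame(
            {
                "term": list(self.coefficients),
                "estimate": list(self.coefficients.values()),
                "se": [self.standard_errors[t] for t in self.coefficients],
                self.statistic: [self.z_values[t] for t in self.coefficients],
                "p": [self.p_values[t] for t in self.coefficients],
            }
        )

    def scalars(self) -> dict:
        return {
            "logLik": self.log_likelihood,
            "AIC": self.aic,
            "k": self.dispersion_k,
            "sigma_group": self.random_intercept_sd,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def _as_design(design) -> tuple:
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("design contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(_aliased_column(X, names))
    return X, names


def _aliased_column(X: np.ndarray, names: Sequence[str]) -> str:
    """Name the first column linearly dependent on its predecessors."""
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            return f"design is rank deficient: column {names[j - 1]!r} is aliased"
    return "design is rank deficient"


def _check_counts(counts) -> np.ndarray:
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise InvalidInputError("counts must be a non-empty 1-D vector")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise InvalidInputError("counts must be non-negative integers")
    if np.all(y == 0):
        raise ModelFitError("all counts are zero: NB likelihood is degenerate")
    return y


def nb_loglik(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    """Pointwise NB2 log-likelihood at linear predictor ``eta`` (log mu)."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    if math.isinf(k):
        return stats.poisson.logpmf(y.astype(int), mu)
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1)
        + k * math.log(k)
        + y * eta
        - (k + y) * np.log(k + mu)
    )


def _nll_grad(params: np.ndarray, y: np.ndarray, X: np.ndarray) -> tuple:
    beta, t = params[:-1], params[-1]
    k = math.exp(t)
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1)
        + k * t
        + y * eta
        - (k + y) * np.log(k + mu)
    ).sum()
    w = k * (y - mu) / (k + mu)
    g_beta = X.T @ w
    g_t = k * (
        special.digamma(y + k)
        - special.digamma(k)
        + t
        + 1.0
        - np.log(k + mu)
        - (k + y) / (k + mu)
    ).sum()
    return -ll, -np.concatenate([g_beta, [g_t]])


def _start_values(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    z = np.log(y + 0.5)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    m, v = y.mean(), y.var()
    k0 = m * m / (v - m) if v > m * 1.001 else K_MAX / 10
    k0 = float(np.clip(k0, K_MIN * 10, K_MAX / 10))
    return np.concatenate([beta0, [math.log(k0)]])


def _wald(names, est, se):
    z = {n: e / s if s > 0 else math.nan for n, e, s in zip(names, est, se)}
    p = {n: 2 * stats.norm.sf(abs(v)) if math.isfinite(v) else math.nan for n, v in z.items()}
    return z, p


def _se_from_hessian(nll, params, n_beta, at_boundary):
    """SEs from the observed information; profile out bounded parameters
    whose Hessian rows are degenerate at a boundary."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = numdiff.approx_hess(params, nll)
    idx = list(range(len(params)))
    if at_boundary:
        idx = list(range(n_beta))
        H = H[np.ix_(idx, idx)]
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    var = np.clip(np.diag(cov), 0, None)
    se = np.full(len(params), math.nan)
    se[idx] = np.sqrt(var)
    return se


def fit_nb_glm(counts, design) -> ModelFit:
    """Maximum-likelihood NB2 regression with a log link.

    Parameters
    ----------
    counts
        Non-negative integer response vector.
    design
        DataFrame (column names become term names) or 2-D array including
        the intercept column.
    """
    y = _check_counts(counts)
    X, names = _as_design(design)
    if len(y) != X.shape[0]:
        raise InvalidInputError("counts and design have different lengths")

    x0 = _start_values(y, X)
    bounds = [(None, None)] * X.shape[1] + [_LOG_K_BOUNDS]
    res = optimize.minimize(
        _nll_grad,
        x0,
        args=(y, X),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": MAX_ITER, "ftol": LL_RTOL * 1e-2, "gtol": 1e-7},
    )
    params = res.x
    t_hat = params[-1]
    k_hat = math.exp(t_hat)
    boundary = (
        t_hat <= _LOG_K_BOUNDS[0] + 1e-6 or t_hat >= _LOG_K_BOUNDS[1] - 1e-6
    )
    nll = lambda p: _nll_grad(p, y, X)[0]
    se = _se_from_hessian(nll, params, X.shape[1], boundary)
    est = params[: X.shape[1]]
    coefficients = dict(zip(names, est.tolist()))
    standard_errors = dict(zip(names, se[: X.shape[1]].tolist()))
    z, p = _wald(names, est, se[: X.shape[1]])
    ll = -res.fun
    n_params = X.shape[1] + 1
    return ModelFit(
        coefficients=coefficients,
        standard_errors=standard_errors,
        z_values=z,
        p_values=p,
        log_likelihood=ll,
        aic=2 * n_params - 2 * ll,
        dispersion_k=k_hat,
        n_obs=len(y),
        converged=bool(res.success),
        n_params=n_params,
        dispersion_at_boundary=boundary,
        method="nb_glm",
    )


# ---------------------------------------------------------------------------
# NB GLMM: single Gaussian random intercept, adaptive Gauss-Hermite
# ---------------------------------------------------------------------------


def _group_structure(group_labels) -> tuple:
    labels = pd.Series(group_labels).astype(str).to_numpy()
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    starts = np.flatnonzero(
        np.concatenate([[True], sorted_labels[1:] != sorted_labels[:-1]])
    )
    return order, starts, sorted_labels[starts]


def _glmm_nll_factory(y, X, order, starts, n_quad):
    ys = y[order]
    Xs = X[order]
    nodes, weights = hermgauss(n_quad)
    log_w = np.log(weights)
    n_groups = len(starts)

    def nll(params: np.ndarray) -> float:
        beta, t, sigma = params[:-2], params[-2], params[-1]
        k = math.exp(t)
        eta0 = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
        if sigma < 1e-6:
            return -nb_loglik(ys, eta0, k).sum()
        inv_var = 1.0 / (sigma * sigma)

        # per-group Laplace mode via damped Newton (all groups vectorized)
        b = np.zeros(n_groups)
        for _ in range(30):
            b_obs = np.repeat(b, np.diff(np.append(starts, len(ys))))
            mu = np.exp(np.clip(eta0 + b_obs, -_ETA_CLIP, _ETA_CLIP))
            score_obs = k * (ys - mu) / (k + mu)
            curv_obs = k * mu * (k + ys) / (k + mu) ** 2
            g = np.add.reduceat(score_obs, starts) - b * inv_var
            h = -np.add.reduceat(curv_obs, starts) - inv_var
            step = np.clip(-g / h, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(g)) < 1e-9:
                break
        b_obs = np.repeat(b, np.diff(np.append(starts, len(ys))))
        mu = np.exp(np.clip(eta0 + b_obs, -_ETA_CLIP, _ETA_CLIP))
        curv_obs = k * mu * (k + ys) / (k + mu) ** 2
        neg_f2 = np.add.reduceat(curv_obs, starts) + inv_var
        tau = 1.0 / np.sqrt(neg_f2)

        # adaptive GH: integral = sqrt(2)*tau * sum_j w_j e^{x_j^2} e^{f(b_hat + sqrt2 tau x_j)}
        log_terms = np.empty((n_quad, n_groups))
        for j, x in enumerate(nodes):
            bj = b + math.sqrt(2.0) * tau * x
            bj_obs = np.repeat(bj, np.diff(np.append(starts, len(ys))))
            f = np.add.reduceat(
                nb_loglik(ys, eta0 + bj_obs, k), starts
            ) - 0.5 * bj * bj * inv_var
            log_terms[j] = log_w[j] + x * x + f
        log_int = special.logsumexp(log_terms, axis=0) + 0.5 * math.log(2.0) + np.log(tau)
        ll = (log_int - 0.5 * math.log(2 * math.pi) - math.log(sigma)).sum()
        return -ll

    return nll


def fit_nb_glmm(counts, design, group_labels, n_quad: int = 5) -> ModelFit:
    """NB2 regression with a per-group Gaussian random intercept.

    The marginal likelihood integrates the random intercept by adaptive
    Gauss-Hermite quadrature (``n_quad`` nodes, Laplace-centred).  With a
    single group the model is unidentifiable and the fixed-effects GLM is
    returned with a warning; an estimated group SD of ~0 likewise collapses
    to the GLM solution.
    """
    y = _check_counts(counts)
    X, names = _as_design(design)
    if len(y) != X.shape[0]:
        raise InvalidInputError("counts and design have different lengths")
    order, starts, group_names = _group_structure(group_labels)
    if len(group_names) < 2:
        warnings.warn("single group: falling back to fit_nb_glm", stacklevel=2)
        return fit_nb_glm(counts, design)

    glm = fit_nb_glm(counts, design)
    x0 = np.concatenate(
        [
            [glm.coefficients[n] for n in names],
            [math.log(min(max(glm.dispersion_k, K_MIN * 10), K_MAX / 10))],
            [0.3],
        ]
    )
    nll = _glmm_nll_factory(y, X, order, starts, n_quad)
    bounds = [(None, None)] * X.shape[1] + [_LOG_K_BOUNDS, (0.0, _SIGMA_MAX)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": MAX_ITER, "ftol": LL_RTOL * 1e-2, "gtol": 1e-6},
        )
    params = res.x
    k_hat = math.exp(params[-2])
    sigma_hat = params[-1]
    boundary = (
        params[-2] <= _LOG_K_BOUNDS[0] + 1e-6
        or params[-2] >= _LOG_K_BOUNDS[1] - 1e-6
        or sigma_hat <= 1e-6
    )
    se = _se_from_hessian(nll, params, X.shape[1], boundary)
    est = params[: X.shape[1]]
    z, p = _wald(names, est, se[: X.shape[1]])
    ll = -res.fun
    n_params = X.shape[1] + 2
    return ModelFit(
        coefficients=dict(zip(names, est.tolist())),
        standard_errors=dict(zip(names, se[: X.shape[1]].tolist())),
        z_values=z,
        p_values=p,
        log_likelihood=ll,
        aic=2 * n_params - 2 * ll,
        dispersion_k=k_hat,
        n_obs=len(y),
        converged=bool(res.success),
        n_params=n_params,
        random_intercept_sd=float(sigma_hat),
        dispersion_at_boundary=boundary,
        method="nb_glmm",
    )


def fit_lmm(response, design, group_labels=None) -> ModelFit:
    """Gaussian linear (mixed) model: REML random intercept, OLS fallback.

    Test statistics are t with residual degrees of freedom
    ``n - n_fixed_effects``, matching the reporting convention of
    length-balance checks.
    """
    import statsmodels.api as sm

    yv = np.asarray(response, dtype=float)
    X, names = _as_design(design)
    if len(yv) != X.shape[0]:
        raise InvalidInputError("response and design have different lengths")
    n, p_fixed = X.shape
    df_resid = n - p_fixed

    groups = None
    if group_labels is not None:
        groups = pd.Series(group_labels).astype(str)
        if groups.nunique() < 2:
            groups = None

    sigma_re = None
    if groups is None:
        ols = sm.OLS(yv, X).fit()
        est, se = ols.params, ols.bse
        llf = ols.llf
        n_params = p_fixed + 1  # + residual variance
        converged = True
        method = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = sm.MixedLM(yv, X, groups=groups.to_numpy())
                mres = md.fit(reml=True, method="lbfgs", maxiter=200)
                est, se = np.asarray(mres.fe_params), np.asarray(mres.bse_fe)
                llf = mres.llf
                sigma_re = float(np.sqrt(max(float(np.squeeze(mres.cov_re)), 0.0)))
                converged = bool(mres.converged)
                n_params = p_fixed + 2  # + residual and group variances
                method = "lmm_reml"
            except Exception:  # singular random-effects structure
                ols = sm.OLS(yv, X).fit()
                est, se = ols.params, ols.bse
                llf = ols.llf
                n_params = p_fixed + 1
                converged = True
                method = "ols"

    tvals = {
        nme: (e / s if s > 0 else (0.0 if e == 0 else math.nan))
        for nme, e, s in zip(names, est, se)
    }
    pvals = {
        nme: 2 * stats.t.sf(abs(t), df_resid) if math.isfinite(t) else math.nan
        for nme, t in tvals.items()
    }
    return ModelFit(
        coefficients=dict(zip(names, np.asarray(est).tolist())),
        standard_errors=dict(zip(names, np.asarray(se).tolist())),
        z_values=tvals,
        p_values=pvals,
        log_likelihood=float(llf),
        aic=2 * n_params - 2 * float(llf),
        dispersion_k=math.inf,
        n_obs=n,
        converged=converged,
        n_params=n_params,
        random_intercept_sd=sigma_re,
        statistic="t",
        df_resid=df_resid,
        method=method,
    )


def compare_aic(fit_a: ModelFit, fit_b: ModelFit, margin: float = 2.0) -> dict:
    """AIC model choice with a support margin (default 2 units).

    ``better`` is ``"a"`` iff ``aic_a <= aic_b - margin`` (symmetrically for
    ``"b"``), else ``"tie"``; ``delta`` is ``aic_a - aic_b``.
    """
    if fit_a.n_obs != fit_b.n_obs:
        raise InvalidInputError("cannot compare AIC across different data")
    delta = fit_a.aic - fit_b.aic
    if delta <= -margin:
        better = "a"
    elif delta >= margin:
        better = "b"
    else:
        better = "tie"
    return {"better": better, "delta": delta}
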