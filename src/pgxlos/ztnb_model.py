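"""Zero-truncated negative binomial (ZTNB) regression for length of stay.

Hospital length of stay is a strictly positive count: a retained
admission lasts at least one day, so the natural model is an NB2
negative binomial conditioned on ``y >= 1``. With mean ``mu = exp(x'b)``
and dispersion ``theta`` (variance ``mu + mu^2/theta``),

    P(Y = y | Y >= 1) = NB2(y; mu, theta) / (1 - NB2(0; mu, theta)),
    NB2(0; mu, theta) = (theta / (theta + mu))^theta.

Exponentiated coefficients are rate ratios: the multiplicative change in
expected (untruncated) LOS per unit covariate change. Fitting maximizes
the ZTNB log-likelihood jointly over ``(b, log theta)`` by quasi-Newton
from a Poisson warm start; the covariance is the inverse observed
information at the optimum, and confidence intervals are 95% Wald.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import qr as _qr

__all__ = [
    "ztnb_log_pmf",
    "ztnb_truncated_mean",
    "solve_mu_for_truncated_mean",
    "ztnb_rvs",
    "ZtnbFit",
    "fit_ztnb",
    "rate_ratio_table",
]

_GRAD_TOL = 1e-6  # infinity-norm of the per-observation-mean score
_LOG2 = np.log(2.0)


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x < 0, stable near both 0 and -inf."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x > -_LOG2  # exp(x) near 1: use expm1
    out[small] = np.log(-np.expm1(x[small]))
    out[~small] = np.log1p(-np.exp(x[~small]))
    return out


def ztnb_log_pmf(y, mu, theta):
    """Log pmf of the zero-truncated NB2 distribution.

    Vectorized over any broadcastable combination of ``y >= 1``,
    ``mu > 0``, ``theta > 0``; stable for large ``theta`` (Poisson limit)
    and large ``y`` via log-gamma arithmetic.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(y < 1) or np.any(y != np.floor(y)):
        raise ValueError("zero-truncated support requires integer y >= 1")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    log_ratio = np.log(theta) - np.log(theta + mu)  # log(theta/(theta+mu)) < 0
    log_nb = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * log_ratio
        + y * (np.log(mu) - np.log(theta + mu))
    )
    log_p0 = theta * log_ratio
    return log_nb - _log1mexp(log_p0)


def ztnb_truncated_mean(mu, theta):
    """E[Y | Y >= 1] = mu / (1 - P0) for the NB2 with mean ``mu``."""
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    log_p0 = theta * (np.log(theta) - np.log(theta + mu))
    return mu / (-np.expm1(log_p0))


def solve_mu_for_truncated_mean(target: float, theta: float) -> float:
    """Invert the truncated mean: the ``mu`` whose ZTNB mean is ``target``.

    ``target`` must exceed 1 (the truncated mean tends to 1 as mu -> 0).
    """
    if target <= 1.0:
        raise ValueError("truncated mean is always > 1")
    lo, hi = 1e-8, max(4.0 * target, 10.0)
    return float(optimize.brentq(
        lambda m: ztnb_truncated_mean(m, theta) - target, lo, hi, xtol=1e-10
    ))


def ztnb_rvs(mu, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the zero-truncated NB2 by gamma–Poisson mixing with
    rejection of zeros (the fitted likelihood and the sampler agree
    exactly by construction)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    y = np.zeros(mu.shape, dtype=np.int64)
    todo = np.ones(mu.shape, dtype=bool)
    while np.any(todo):
        lam = rng.gamma(theta, mu[todo] / theta)
        y[todo] = rng.poisson(lam)
        todo = y == 0
    return y


# ---------------------------------------------------------------------------
# likelihood + score

def _nll_and_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Mean negative log-likelihood and its gradient in (beta, log theta)."""
    n, p = X.shape
    beta, log_theta = params[:p], params[p]
    theta = np.exp(log_theta)
    eta = X @ beta
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    log_ratio = np.log(theta) - np.log(theta + mu)
    log_p0 = theta * log_ratio
    log_1mp0 = _log1mexp(log_p0)
    ll = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * log_ratio
        + y * (np.log(mu) - np.log(theta + mu))
        - log_1mp0
    )
    # d ll / d mu, then chain through mu = exp(x'b)
    p0_over_1mp0 = np.exp(log_p0 - log_1mp0)
    dmu = (
        y / mu
        - (y + theta) / (theta + mu)
        - theta * p0_over_1mp0 / (theta + mu)
    )
    grad_beta = X.T @ (dmu * mu)
    # d ll / d theta
    dp0_dtheta_term = log_ratio + mu / (theta + mu)  # dP0/dtheta = P0 * this
    dtheta = (
        special.digamma(y + theta)
        - special.digamma(theta)
        + log_ratio
        + mu / (theta + mu)
        - y / (theta + mu)
        + p0_over_1mp0 * dp0_dtheta_term
    )
    grad = np.concatenate([grad_beta, [np.sum(dtheta) * theta]])
    return -np.mean(ll), -grad / n


def _numerical_hessian(params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Observed information of the total NLL by central differences of the
    analytic score."""
    n = X.shape[0]
    k = params.size
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(params[j]))
        up = params.copy(); up[j] += h
        dn = params.copy(); dn[j] -= h
        _, g_up = _nll_and_grad(up, X, y)
        _, g_dn = _nll_and_grad(dn, X, y)
        H[:, j] = (g_up - g_dn) / (2.0 * h)
    H = 0.5 * (H + H.T) * n  # symmetrize; scale mean NLL -> total
    return H


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(columns)
        )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientDesignError(sorted(bad))


@dataclass
class ZtnbFit:
    """Fitted ZTNB regression.

    ``beta`` is on the log scale (intercept first); ``covariance`` covers
    ``(beta, log_theta)``. ``rate_ratios`` holds exp(beta) with 95% Wald
    intervals and two-sided p-values, and is only populated when the
    optimizer converged.
    """

    beta: pd.Series
    theta: float
    covariance: pd.DataFrame
    loglik: float
    converged: bool
    n_obs: int
    grad_norm: float
    n_iter: int

    @property
    def se(self) -> pd.Series:
        names = list(self.beta.index)
        return pd.Series(
            np.sqrt(np.diag(self.covariance.loc[names, names].to_numpy())),
            index=names,
        )

    @property
    def rate_ratios(self) -> pd.DataFrame | None:
        if not self.converged:
            return None
        se = self.se
        z = self.beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "coef": self.beta,
            "se": se,
            "rate_ratio": np.exp(self.beta),
            "ci_low": np.exp(self.beta - 1.959963984540054 * se),
            "ci_high": np.exp(self.beta + 1.959963984540054 * se),
            "p_value": p,
        })


def _poisson_warm_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Poisson IRLS start for beta (ignores truncation; close enough)."""
    import statsmodels.api as sm

    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=50)
    return np.asarray(res.params, dtype=float)


def fit_ztnb(design: pd.DataFrame, y, add_intercept: bool = True) -> ZtnbFit:
    """Maximum-likelihood ZTNB fit of ``y`` (integer days >= 1) on a
    covariate table.

    Deterministic: quasi-Newton (BFGS) on the mean negative
    log-likelihood over ``(beta, log theta)``, started from a Poisson
    regression with a method-of-moments dispersion estimate. Convergence
    requires the score's infinity norm below 1e-6; the covariance is the
    inverse observed information at the optimum. Rank-deficient designs
    are rejected with the collinear columns named.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design))
        design.columns = [f"x{j}" for j in range(design.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != design.shape[0]:
        raise ValueError("y must be one value per design row")
    if np.any(y < 1) or np.any(y != np.floor(y)):
        raise ValueError("LOS outcomes must be integer days >= 1")
    names = list(map(str, design.columns))
    X = design.to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    _check_full_rank(X, names)

    beta0 = _poisson_warm_start(X, y)
    mu0 = np.exp(np.clip(X @ beta0, -30, 30))
    excess = np.sum((y - mu0) ** 2 - mu0)
    theta0 = np.sum(mu0**2) / excess if excess > 0 else 100.0
    theta0 = float(np.clip(theta0, 0.05, 1e4))
    x0 = np.concatenate([beta0, [np.log(theta0)]])

    res = optimize.minimize(
        _nll_and_grad, x0, args=(X, y), jac=True, method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    # Polish with a second pass if the score is not yet small enough.
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > _GRAD_TOL:
        res2 = optimize.minimize(
            _nll_and_grad, res.x, args=(X, y), jac=True, method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
        )
        if res2.fun <= res.fun:
            res = res2
            grad_norm = float(np.max(np.abs(res.jac)))

    params = res.x
    theta = float(np.exp(params[-1]))
    converged = bool(grad_norm < _GRAD_TOL)
    if theta > 5e3:
        # near-Poisson boundary: the likelihood is flat in log theta; a
        # small score there still means a usable optimum, but flag it.
        converged = converged and grad_norm < _GRAD_TOL

    H = _numerical_hessian(params, X, y)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((params.size, params.size), np.nan)
        converged = False
    cov_names = names + ["log_theta"]
    n = X.shape[0]
    return ZtnbFit(
        beta=pd.Series(params[:-1], index=names),
        theta=theta,
        covariance=pd.DataFrame(cov, index=cov_names, columns=cov_names),
        loglik=float(-res.fun * n),
        converged=converged,
        n_obs=int(n),
        grad_norm=grad_norm,
        n_iter=int(res.nit),
    )


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def rate_ratio_table(fit: ZtnbFit, labels: dict[str, str] | None = None
                     ) -> pd.DataFrame:
    """Report rows (one per non-intercept coefficient): rate ratio with
    95% CI and p-value, formatted to two decimals. Requires a converged
    fit."""
    if not fit.converged:
        raise ValueError("refusing to report rate ratios from a non-converged fit")
    rr = fit.rate_ratios
    rows = []
    for name, r in rr.iterrows():
        if name == "intercept":
            continue
        label = (labels or {}).get(name, name)
        rows.append({
            "term": name,
            "label": label,
            "rate_ratio": r["rate_ratio"],
            "ci_low": r["ci_low"],
            "ci_high": r["ci_high"],
            "p_value": r["p_value"],
            "display": (
                f"{r['rate_ratio']:.2f} "
                f"({r['ci_low']:.2f}, {r['ci_high']:.2f})"
            ),
            "p_display": _fmt_p(r["p_value"]),
        })
    return pd.DataFrame(rows)
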