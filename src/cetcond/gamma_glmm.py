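"""Gamma log-link models for right-skewed tissue hormone concentrations.

Two fitters share a common result type:

* :func:`fit_gamma_glm` — fixed-effects gamma GLM (log link) via IRLS
  (statsmodels), with the shape parameter estimated by maximum likelihood
  so that AIC/AICc values are comparable across candidate models.
* :func:`fit_gamma_glmm` — gamma GLM with a Gaussian random intercept per
  individual, estimated by Laplace-approximated maximum likelihood.  The
  inner mode-finding per group is a one-dimensional Newton iteration
  (the conditional log-posterior in the intercept is strictly concave),
  vectorized over groups; the outer optimization is quasi-Newton over
  ``(beta, log sigma_u, log shape)``.

With random-intercept variance near zero the mixed fit collapses to the
fixed-effects GLM.  Marginal (population-averaged) means on the response
scale include the lognormal correction ``exp(sigma_u^2 / 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
import statsmodels.api as sm

from .evaluation import build_design

__all__ = [
    "GammaFitResult",
    "fit_gamma_glm",
    "fit_gamma_glmm",
]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GammaFitResult:
    """Gamma log-link fit: coefficients on the log scale, shape, criteria."""

    terms: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    shape: float
    sigma_u: float  # random-intercept SD on the log scale (0 for plain GLM)
    loglik: float
    n: int
    n_groups: int | None
    mixed: bool
    converged: bool = True
    column_names: list[str] = field(default_factory=list)
    term_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        # coefficients + shape (+ random-intercept SD for mixed fits)
        return len(self.coef) + 1 + (1 if self.mixed else 0)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        k = self.k_params
        denom = self.n - k - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / denom

    @property
    def df_total(self) -> int:
        return self.k_params

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        """Evaluate the stored design columns on new data.

        Columns are rebuilt from their names so factor levels absent from
        ``data`` (e.g. counterfactual predictions with every row set to one
        level) still evaluate correctly.
        """

        def one(colname: str) -> np.ndarray:
            if colname == "Intercept":
                return np.ones(len(data))
            parts = colname.split(":")
            out = np.ones(len(data))
            for part in parts:
                if part.endswith("]") and "[" in part:
                    var, level = part[:-1].split("[", 1)
                    out = out * (data[var].astype(str) == level).to_numpy(float)
                else:
                    out = out * data[part].to_numpy(float)
            return out

        X = np.column_stack([one(c) for c in self.column_names])
        return X @ self.coef.to_numpy()

    def marginal_means(self, data: pd.DataFrame) -> np.ndarray:
        """Population-averaged response-scale means at the given covariates."""
        eta = self.linear_predictor(data)
        return np.exp(eta + 0.5 * self.sigma_u**2)

    def pvalues(self) -> pd.Series:
        from scipy import stats

        z = self.coef / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coef.index)


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, nu: float) -> float:
    """Sum of gamma log-densities with mean mu and shape nu."""
    return float(
        np.sum(
            nu * np.log(nu)
            - special.gammaln(nu)
            + (nu - 1) * np.log(y)
            - nu * np.log(mu)
            - nu * y / mu
        )
    )


def _ml_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximum-likelihood gamma shape given fitted means."""
    res = optimize.minimize_scalar(
        lambda lognu: -_gamma_loglik(y, mu, np.exp(lognu)),
        bounds=(np.log(1e-3), np.log(1e5)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def fit_gamma_glm(
    response: Sequence[float],
    data: pd.DataFrame,
    terms: Sequence[str],
) -> GammaFitResult:
    """Gamma GLM with log link; shape estimated by maximum likelihood."""
    y = np.asarray(response, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive")
    X, names, term_map = build_design(data, list(terms))
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    mu = np.asarray(res.fittedvalues, dtype=float)
    nu = _ml_shape(y, mu)
    ll = _gamma_loglik(y, mu, nu)
    return GammaFitResult(
        terms=tuple(terms),
        coef=pd.Series(np.asarray(res.params, float), index=names),
        se=pd.Series(np.asarray(res.bse, float), index=names),
        shape=nu,
        sigma_u=0.0,
        loglik=ll,
        n=y.size,
        n_groups=None,
        mixed=False,
        column_names=names,
        term_map=term_map,
    )


def _laplace_nll(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    group_sizes: np.ndarray,
    newton_iter: int = 30,
) -> float:
    """Negative Laplace-approximated marginal log-likelihood.

    theta = (beta..., log sigma_u, log shape).  For each group the mode of
    the conditional log-posterior in the random intercept is found by
    Newton iteration on

        g(u) = nu * (-sum_j eta_ij - sum_j y_ij exp(-eta_ij)) - u^2/(2 s^2) + const
    """
    p = X.shape[1]
    beta = theta[:p]
    sigma = np.exp(theta[p])
    nu = np.exp(theta[p + 1])
    eta0 = X @ beta
    # S_i = sum_j y_ij * exp(-x_ij beta): sufficient statistic per group
    S = np.bincount(group_idx, weights=y * np.exp(-eta0), minlength=n_groups)
    n_i = group_sizes
    s2 = sigma * sigma

    u = np.zeros(n_groups)
    for _ in range(newton_iter):
        e = np.exp(-u)
        grad = nu * (e * S - n_i) - u / s2
        hess = -nu * e * S - 1.0 / s2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-12:
            break

    e = np.exp(-u)
    # conditional gamma log-likelihood at the mode
    ll_cond = (
        y.size * (nu * np.log(nu) - special.gammaln(nu))
        + (nu - 1) * np.sum(np.log(y))
        - nu * (np.sum(eta0) + np.sum(u * n_i))
        - nu * np.sum(e * S)
    )
    ll_prior = -0.5 * np.sum(u * u) / s2 - 0.5 * n_groups * np.log(2 * np.pi * s2)
    H = nu * e * S + 1.0 / s2  # negative second derivative at the mode
    ll = ll_cond + ll_prior + 0.5 * n_groups * _LOG2PI - 0.5 * np.sum(np.log(H))
    return -ll


def fit_gamma_glmm(
    response: Sequence[float],
    data: pd.DataFrame,
    terms: Sequence[str],
    groups: Sequence,
    min_sigma: float = 1e-4,
) -> GammaFitResult:
    """Gamma log-link model with a per-group Gaussian random intercept.

    Laplace-approximated maximum likelihood; starting values come from the
    fixed-effects GLM.  Standard errors are from the finite-difference
    Hessian of the Laplace log-likelihood at the optimum.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive")
    X, names, term_map = build_design(data, list(terms))
    p = X.shape[1]
    codes, levels = pd.factorize(np.asarray(groups))
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("need >= 2 groups for a random intercept")
    group_sizes = np.bincount(codes, minlength=n_groups).astype(float)

    glm = fit_gamma_glm(y, data, terms)
    theta0 = np.concatenate(
        [glm.coef.to_numpy(), [np.log(0.3)], [np.log(max(glm.shape, 1e-2))]]
    )
    args = (y, X, codes, n_groups, group_sizes)
    res = optimize.minimize(
        _laplace_nll,
        theta0,
        args=args,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(np.log(min_sigma), np.log(10.0)), (np.log(1e-3), np.log(1e5))],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success:
        logger.warning("gamma GLMM optimizer message: %s", res.message)
    theta = res.x
    ll = -float(res.fun)
    se = _fd_se(lambda t: _laplace_nll(t, *args), theta)[:p]
    return GammaFitResult(
        terms=tuple(terms),
        coef=pd.Series(theta[:p], index=names),
        se=pd.Series(se, index=names),
        shape=float(np.exp(theta[p + 1])),
        sigma_u=float(np.exp(theta[p])),
        loglik=ll,
        n=y.size,
        n_groups=n_groups,
        mixed=True,
        converged=bool(res.success),
        column_names=names,
        term_map=term_map,
    )


def _fd_se(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Standard errors from a central finite-difference Hessian of the NLL."""
    k = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(theta + ei + ej)
                    - fun(theta + ei - ej)
                    - fun(theta - ei + ej)
                    + fun(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se
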