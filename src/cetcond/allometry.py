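"""Mass-length allometry: log-log OLS, standardized major axis, and
nonlinear power-law fits.

The central model is ``mass = delta + alpha * length**beta``: mass is a
power function of length plus an intercept.  When the fitted exponent
``beta`` differs from 1, a size-independent condition ratio requires a
scaling exponent other than 1 — this is the diagnostic that motivates
mass/length^2 over mass/length for animals whose mass scales roughly with
the square of body length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LogAllometryFit",
    "SMAFit",
    "AllometricFit",
    "SingularFitError",
    "UndefinedSMAError",
    "fit_log_allometry",
    "fit_sma",
    "fit_nonlinear_allometry",
]


class SingularFitError(ValueError):
    """Regression is singular (e.g. all lengths identical)."""


class UndefinedSMAError(ValueError):
    """SMA slope undefined because ln-mass and ln-length are uncorrelated."""


@dataclass(frozen=True)
class LogAllometryFit:
    """OLS fit of ln(mass) on ln(length).

    ``a`` is the back-transformed intercept and ``b`` the slope, so the
    fitted curve is ``mass* = a * length**b``.  ``residuals`` are the
    per-record log-scale residuals; they are the residual condition index
    and by the OLS normal equations they sum to zero.
    """

    a: float
    b: float
    intercept_log: float
    residuals: np.ndarray
    n: int

    def predict_mass(self, length) -> np.ndarray:
        return self.a * np.asarray(length, dtype=float) ** self.b


@dataclass(frozen=True)
class SMAFit:
    """Standardized major axis fit of ln(mass) on ln(length).

    The SMA slope is the OLS slope divided by the Pearson correlation,
    equivalently sign(r) * sd(lnM)/sd(lnL); it treats both variables
    symmetrically.  ``l0`` is the reference length (arithmetic mean of the
    lengths) used by the scaled mass index.
    """

    b_ols: float
    r: float
    b_sma: float
    l0: float
    n: int


@dataclass(frozen=True)
class AllometricFit:
    """Nonlinear least-squares fit of mass = delta + alpha * length**beta."""

    delta: float
    alpha: float
    beta: float
    se: dict = field(default_factory=dict)
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)
    ci_level: float = 0.95
    converged: bool = True
    n_used: int = 0
    rss: float = float("nan")

    def predict_mass(self, length) -> np.ndarray:
        return self.delta + self.alpha * np.asarray(length, dtype=float) ** self.beta


def _as_mass_length(mass, length) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(mass, dtype=float)
    length_arr = np.asarray(length, dtype=float)
    if m.shape != length_arr.shape:
        raise ValueError("mass and length must have the same shape")
    if np.any(m <= 0) or np.any(length_arr <= 0):
        raise ValueError("mass and length must be strictly positive")
    return m, length_arr


def fit_log_allometry(mass: Sequence[float], length: Sequence[float]) -> LogAllometryFit:
    """OLS regression of ln(mass) on ln(length).

    Needs at least 3 records with positive mass and length and non-constant
    length.  The residuals returned ARE the residual condition index.
    """
    m, length_arr = _as_mass_length(mass, length)
    if m.size < 3:
        raise ValueError(f"need >= 3 records, got {m.size}")
    lm, ll = np.log(m), np.log(length_arr)
    sxx = np.sum((ll - ll.mean()) ** 2)
    if sxx == 0:
        raise SingularFitError("all lengths identical: log-log OLS is singular")
    b = float(np.sum((ll - ll.mean()) * (lm - lm.mean())) / sxx)
    intercept = float(lm.mean() - b * ll.mean())
    resid = lm - (intercept + b * ll)
    return LogAllometryFit(
        a=math.exp(intercept), b=b, intercept_log=intercept, residuals=resid, n=m.size
    )


def fit_sma(mass: Sequence[float], length: Sequence[float]) -> SMAFit:
    """Standardized major axis regression of ln(mass) on ln(length)."""
    m, length_arr = _as_mass_length(mass, length)
    if m.size < 3:
        raise ValueError(f"need >= 3 records, got {m.size}")
    lm, ll = np.log(m), np.log(length_arr)
    if np.ptp(ll) == 0 or np.ptp(lm) == 0:
        raise SingularFitError("zero variance in ln(mass) or ln(length)")
    r = float(np.corrcoef(ll, lm)[0, 1])
    if r == 0 or not np.isfinite(r):
        raise UndefinedSMAError("ln(mass) and ln(length) are uncorrelated; SMA slope undefined")
    ols = fit_log_allometry(m, length_arr)
    return SMAFit(b_ols=ols.b, r=r, b_sma=ols.b / r, l0=float(length_arr.mean()), n=m.size)


def _power_model(length, delta, alpha, beta):
    return delta + alpha * np.power(length, beta)


def fit_nonlinear_allometry(
    mass: Sequence[float],
    length: Sequence[float],
    ci_level: float = 0.95,
    max_nfev: int = 20000,
) -> AllometricFit:
    """Nonlinear least squares for ``mass = delta + alpha * length**beta``.

    Starting values come from the log-log OLS fit (delta=0,
    alpha=exp(intercept), beta=slope), which is deterministic and close to
    the optimum whenever the power law is a reasonable description.
    Confidence intervals are asymptotic (Wald) from the Jacobian at the
    optimum.
    """
    m, length_arr = _as_mass_length(mass, length)
    if m.size < 10:
        raise ValueError(f"need >= 10 records for the nonlinear fit, got {m.size}")
    ols = fit_log_allometry(m, length_arr)
    p0 = [0.0, ols.a, ols.b]
    try:
        popt, pcov = optimize.curve_fit(
            _power_model,
            length_arr,
            m,
            p0=p0,
            maxfev=max_nfev,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError:
        return AllometricFit(
            delta=float("nan"),
            alpha=float("nan"),
            beta=float("nan"),
            converged=False,
            n_used=m.size,
            ci_level=ci_level,
        )
    delta, alpha, beta = (float(v) for v in popt)
    resid = m - _power_model(length_arr, *popt)
    rss = float(resid @ resid)
    dof = max(m.size - 3, 1)
    names = ("delta", "alpha", "beta")
    se = {k: float(np.sqrt(max(pcov[i, i], 0.0))) for i, k in enumerate(names)}
    tcrit = stats.t.ppf(0.5 + ci_level / 2, dof)
    est = dict(zip(names, (delta, alpha, beta)))
    ci_low = {k: est[k] - tcrit * se[k] for k in names}
    ci_high = {k: est[k] + tcrit * se[k] for k in names}
    return AllometricFit(
        delta=delta,
        alpha=alpha,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        converged=True,
        n_used=m.size,
        rss=rss,
    )
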