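"""Four-parameter logistic (4PL) immunoassay calibration.

Competitive ELISA orientation: the optical response is highest at zero
analyte (``a``), falls sigmoidally with concentration, and approaches the
infinite-dose asymptote ``d``; ``c`` is the inflection concentration and
``b`` the slope factor:

    response(x) = d + (a - d) / (1 + (x / c)**b)

The inverse is closed-form, so quantification is exact wherever the
response lies strictly between the asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FourPLParams",
    "LOD_NGML",
    "fourpl_response",
    "fit_4pl",
    "invert_4pl",
    "NonConvergenceError",
    "OutOfRangeError",
]

#: assay sensitivity (ng/ml); inverted values below this are below the
#: limit of detection and flagged, not discarded
LOD_NGML = 2.5


class NonConvergenceError(RuntimeError):
    """The 4PL least-squares fit failed to converge."""


class OutOfRangeError(ValueError):
    """Response outside the open interval between the curve asymptotes."""


@dataclass(frozen=True)
class FourPLParams:
    """4PL curve parameters (competitive orientation: a > d)."""

    a: float  # response at zero concentration
    d: float  # response at infinite concentration
    c: float  # inflection concentration, ng/ml
    b: float  # slope factor

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"inflection concentration c must be > 0, got {self.c}")
        if self.a == self.d:
            raise ValueError("a and d must differ (flat curve has no inverse)")


def fourpl_response(x, params: FourPLParams) -> np.ndarray:
    """Forward curve; strictly monotone in concentration on (0, inf)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / params.c) ** params.b, 0.0)
    return params.d + (params.a - params.d) / (1.0 + ratio)


def _model(x, a, d, c, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x > 0, (x / c) ** b, 0.0)
    return d + (a - d) / (1.0 + ratio)


@dataclass(frozen=True)
class FourPLFit:
    params: FourPLParams
    rss: float
    residuals: np.ndarray
    monotone_standards: bool


def fit_4pl(concentration, response) -> FourPLFit:
    """Least-squares 4PL fit to standard-curve points.

    Needs >= 5 standards spanning the range, including the zero standard.
    Non-monotone standards are tolerated (noise) and noted on the result.
    """
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size < 5:
        raise ValueError(f"need >= 5 standard points, got {x.size}")
    if not np.any(x == 0):
        raise ValueError("standard curve must include the zero standard")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    monotone = bool(np.all(np.diff(ys) <= 0) or np.all(np.diff(ys) >= 0))

    a0, d0 = float(ys[0]), float(ys[-1])
    mid = (a0 + d0) / 2.0
    pos = xs > 0
    c0 = float(np.interp(mid, ys[pos][::-1], xs[pos][::-1])) if a0 > d0 else float(
        np.interp(mid, ys[pos], xs[pos])
    )
    c0 = c0 if np.isfinite(c0) and c0 > 0 else float(np.median(xs[pos]))
    p0 = [a0, d0, c0, 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _model, x, y, p0=p0, maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
    except RuntimeError as exc:
        raise NonConvergenceError(f"4PL fit did not converge: {exc}") from exc
    a, d, c, b = (float(v) for v in popt)
    if c < 0:  # (c,b) sign ambiguity: (x/c)^b defined for c>0 only
        raise NonConvergenceError("4PL fit converged to negative inflection")
    params = FourPLParams(a=a, d=d, c=c, b=b)
    resid = y - fourpl_response(x, params)
    return FourPLFit(
        params=params,
        rss=float(resid @ resid),
        residuals=resid,
        monotone_standards=monotone,
    )


def invert_4pl(params: FourPLParams, response, lod: float = LOD_NGML):
    """Concentration from response: x = c * ((a - y)/(y - d))**(1/b).

    Returns ``(concentration, below_lod_flag)``; raises
    :class:`OutOfRangeError` for responses at or beyond the asymptotes.
    """
    y = np.asarray(response, dtype=float)
    lo, hi = min(params.a, params.d), max(params.a, params.d)
    if np.any((y <= lo) | (y >= hi)):
        bad = y[(y <= lo) | (y >= hi)]
        raise OutOfRangeError(
            f"response(s) {bad} outside the open asymptote interval ({lo}, {hi})"
        )
    x = params.c * ((params.a - y) / (y - params.d)) ** (1.0 / params.b)
    below = x < lod
    if np.isscalar(response) or np.ndim(response) == 0:
        return float(x), bool(below)
    return x, below
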