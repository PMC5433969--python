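"""The ten morphometric body-condition indices.

Simple ratio indices (blubber depth, blubber/girth, blubber/length,
girth/length, mass/length, Fulton's K = mass/length^3, Quetelet's
BMI = mass/length^2) are per-record arithmetic.  The remaining three
require a population-level fit: relative condition Kn (observed over
allometrically predicted mass), the residual index (log-log OLS
residuals), and the scaled mass index (mass standardized to the mean
population length with the SMA scaling exponent).

Units follow the interchange convention: mass kg, length/girth cm,
blubber mm.  Quetelet's index is therefore in kg/cm^2, so a healthy
adult porpoise sits near 0.002.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import (
    AllometricFit,
    LogAllometryFit,
    SMAFit,
    fit_log_allometry,
    fit_nonlinear_allometry,
    fit_sma,
)
from .records import MissingFieldError, MorphRecord

__all__ = [
    "SIMPLE_INDICES",
    "ALL_INDICES",
    "POWER_RATIO_EXPONENTS",
    "compute_simple_index",
    "relative_condition",
    "residual_index",
    "scaled_mass_index",
    "build_index_table",
    "size_independence",
    "UndefinedCorrelationError",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined because one vector has zero variance."""


def _require(rec: MorphRecord, *fields: str) -> None:
    rec.require(*fields)
    for f in fields:
        v = getattr(rec, f)
        if f in ("length", "girth") and v == 0:
            raise ValueError(f"{f} must be nonzero for record {rec.id!r}")


#: per-record ratio/power formulas: name -> (required fields, function)
SIMPLE_INDICES = {
    "ventral_blubber": (("blubber_ventral",), lambda r: r.blubber_ventral),
    "blubber_over_girth": (
        ("blubber_ventral", "girth"),
        lambda r: r.blubber_ventral / r.girth,
    ),
    "blubber_over_length": (
        ("blubber_ventral", "length"),
        lambda r: r.blubber_ventral / r.length,
    ),
    "girth_over_length": (("girth", "length"), lambda r: r.girth / r.length),
    "mass_over_length": (("mass", "length"), lambda r: r.mass / r.length),
    "fulton_K": (("mass", "length"), lambda r: r.mass / r.length**3),
    "quetelet": (("mass", "length"), lambda r: r.mass / r.length**2),
}

#: mass/length^k family members and their exponents (for the
#: size-independence override in index ranking)
POWER_RATIO_EXPONENTS = {"mass_over_length": 1, "quetelet": 2, "fulton_K": 3}

ALL_INDICES = list(SIMPLE_INDICES) + [
    "relative_condition",
    "residual_index",
    "scaled_mass",
]


def compute_simple_index(record: MorphRecord, which: str) -> float:
    """One ratio/power index for one record.

    Raises :class:`~cetcond.records.MissingFieldError` naming the absent
    field, or ``ValueError`` for a zero denominator.
    """
    try:
        fields, fn = SIMPLE_INDICES[which]
    except KeyError:
        raise KeyError(
            f"unknown simple index {which!r}; choose from {sorted(SIMPLE_INDICES)}"
        ) from None
    _require(record, *fields)
    return float(fn(record))


def residual_index(
    mass: Sequence[float], length: Sequence[float]
) -> tuple[np.ndarray, LogAllometryFit]:
    """Residuals of the OLS regression of ln(mass) on ln(length)."""
    fit = fit_log_allometry(mass, length)
    return fit.residuals, fit


def relative_condition(
    mass: Sequence[float], length: Sequence[float]
) -> tuple[np.ndarray, LogAllometryFit]:
    """Kn = observed mass / mass predicted by the fitted power law.

    The predicting curve is the log-scale OLS fit back-transformed, so the
    geometric mean of Kn over the fitting set is exactly 1.
    """
    fit = fit_log_allometry(mass, length)
    kn = np.exp(fit.residuals)
    return kn, fit


def scaled_mass_index(
    mass: Sequence[float],
    length: Sequence[float],
    l0: float | None = None,
) -> tuple[np.ndarray, SMAFit]:
    """Scaled mass index: M_i * (L0 / L_i) ** b_SMA.

    ``l0`` defaults to the arithmetic mean length of the records supplied;
    pass an explicit reference length for cross-dataset comparability.
    """
    sma = fit_sma(mass, length)
    ref = sma.l0 if l0 is None else float(l0)
    m = np.asarray(mass, dtype=float)
    length_arr = np.asarray(length, dtype=float)
    smi = m * (ref / length_arr) ** sma.b_sma
    if l0 is not None:
        sma = SMAFit(b_ols=sma.b_ols, r=sma.r, b_sma=sma.b_sma, l0=ref, n=sma.n)
    return smi, sma


def size_independence(index_values: Sequence[float], lengths: Sequence[float]):
    """Pearson correlation of a condition index against body length.

    A good condition index should be uncorrelated with length; returns
    ``(r, p_value)`` from the two-sided test.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if x.size != y.size:
        raise ValueError("index and length vectors must be the same size")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "constant index or length vector: correlation undefined"
        )
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class IndexTableResult:
    """Per-animal index table plus the population-level fits behind it."""

    table: pd.DataFrame
    log_fit: LogAllometryFit | None
    sma_fit: SMAFit | None
    nls_fit: AllometricFit | None
    excluded: dict[str, int]


def build_index_table(
    records: Sequence[MorphRecord],
    fit_nls: bool = True,
    l0: float | None = None,
) -> IndexTableResult:
    """Compute all ten condition indices for a set of records.

    Records missing a field are excluded from that index only (count
    logged per index), never dropped globally.  The population-level fits
    (log-log OLS, SMA, and optionally the nonlinear power law) use every
    record with positive mass and length.
    """
    table = pd.DataFrame(
        {
            "cod_class": [r.cod_class for r in records],
            "age_class": [r.age_class for r in records],
            "season": [r.season for r in records],
            "sex": [r.sex for r in records],
            "mass_kg": [r.mass for r in records],
            "length_cm": [r.length for r in records],
        },
        index=pd.Index([r.id for r in records], name="id"),
    )

    excluded: dict[str, int] = {}
    for name in SIMPLE_INDICES:
        vals, n_missing = [], 0
        for r in records:
            try:
                vals.append(compute_simple_index(r, name))
            except MissingFieldError:
                vals.append(np.nan)
                n_missing += 1
        table[name] = vals
        if n_missing:
            excluded[name] = n_missing
            logger.info("index %s: excluded %d records with missing fields", name, n_missing)

    mass = np.array([r.mass for r in records], dtype=float)
    length = np.array([r.length for r in records], dtype=float)
    log_fit = sma_fit = nls_fit = None
    if len(records) >= 3:
        resid, log_fit = residual_index(mass, length)
        table["residual_index"] = resid
        table["relative_condition"] = np.exp(resid)
        smi, sma_fit = scaled_mass_index(mass, length, l0=l0)
        table["scaled_mass"] = smi
    if fit_nls and len(records) >= 10:
        nls_fit = fit_nonlinear_allometry(mass, length)
    return IndexTableResult(
        table=table, log_fit=log_fit, sma_fit=sma_fit, nls_fit=nls_fit, excluded=excluded
    )
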