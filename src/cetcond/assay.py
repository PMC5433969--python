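"""Assay bookkeeping: tissue-concentration correction, CV quality gates,
and the plate quantification chain.

A plate file holds standard-curve wells, duplicate sample wells, and
control wells.  Quantification fits the 4PL standard curve per plate,
inverts each sample response to ng/ml, averages duplicates, and converts
to ng/g of tissue using the extract resuspension volume, the subsample
mass, and an extraction-efficiency correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fourpl import LOD_NGML, FourPLFit, fit_4pl, invert_4pl
from .records import SchemaError

__all__ = [
    "RESUSPENSION_VOLUME_ML",
    "INTRA_CV_LIMIT",
    "INTER_CV_LIMIT",
    "PLATE_CSV_COLUMNS",
    "to_tissue_concentration",
    "duplicate_cv",
    "assay_cv",
    "quantify_plate",
    "read_plate_csv",
]

logger = logging.getLogger(__name__)

#: extract resuspension volume (ml) used to convert ng/ml to ng per extract
RESUSPENSION_VOLUME_ML = 0.5

#: acceptable mean CV limits (%): intra-assay (duplicates) and inter-assay
#: (control extracts across plates)
INTRA_CV_LIMIT = 10.0
INTER_CV_LIMIT = 20.0

PLATE_CSV_COLUMNS = ["well", "sample_id", "role", "concentration_ngml", "response"]


def to_tissue_concentration(
    conc_ngml,
    tissue_mass_g,
    efficiency=1.0,
    resuspension_volume_ml: float = RESUSPENSION_VOLUME_ML,
):
    """ng/g of tissue = ng/ml * volume / tissue mass / extraction efficiency."""
    eff = np.asarray(efficiency, dtype=float)
    mass = np.asarray(tissue_mass_g, dtype=float)
    if np.any(eff <= 0) or np.any(eff > 1):
        raise ValueError("efficiency must lie in (0, 1]")
    if np.any(mass <= 0):
        raise ValueError("tissue mass must be > 0")
    out = np.asarray(conc_ngml, dtype=float) * resuspension_volume_ml / mass / eff
    return float(out) if np.ndim(conc_ngml) == 0 else out


def duplicate_cv(values) -> float:
    """Percent CV (100 * sd / mean, sample sd) of one duplicate set."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("duplicate mean is zero; CV undefined")
    return float(100.0 * v.std(ddof=1) / m)


def assay_cv(
    duplicates: dict[str, np.ndarray] | None = None,
    controls_by_plate: dict[str, np.ndarray] | None = None,
) -> dict:
    """Intra- and inter-assay coefficients of variation with QC flags.

    ``duplicates`` maps sample id -> within-plate duplicate concentrations;
    ``controls_by_plate`` maps control extract id -> per-plate mean
    concentrations of that extract across plates.  Intra CV is the mean of
    per-sample duplicate CVs (limit 10%); inter CV the mean of per-control
    across-plate CVs (limit 20%).  Pairs with zero mean are excluded with a
    log entry.
    """
    out: dict = {}
    if duplicates:
        cvs = []
        for sid, vals in duplicates.items():
            try:
                cvs.append(duplicate_cv(vals))
            except ZeroDivisionError:
                logger.warning("duplicate set %s has zero mean; excluded from CV", sid)
        out["intra_cv_percent"] = float(np.mean(cvs)) if cvs else np.nan
        out["intra_pass"] = bool(out["intra_cv_percent"] < INTRA_CV_LIMIT)
    if controls_by_plate:
        cvs = []
        for cid, vals in controls_by_plate.items():
            if len(np.atleast_1d(vals)) < 2:
                continue
            try:
                cvs.append(duplicate_cv(vals))
            except ZeroDivisionError:
                logger.warning("control %s has zero mean; excluded from CV", cid)
        out["inter_cv_percent"] = float(np.mean(cvs)) if cvs else np.nan
        out["inter_pass"] = bool(out["inter_cv_percent"] < INTER_CV_LIMIT)
    return out


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "well": str, "role": str})
    missing = [c for c in PLATE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"plate CSV {path} missing columns {missing}; expected {PLATE_CSV_COLUMNS}"
        )
    return df


@dataclass
class PlateResult:
    """Quantified plate: per-sample ng/ml means plus QC metadata."""

    fit: FourPLFit
    samples: pd.DataFrame  # sample_id, conc_ngml (duplicate mean), cv, below_lod
    controls: pd.DataFrame
    flags: dict = field(default_factory=dict)


def quantify_plate(plate: pd.DataFrame) -> PlateResult:
    """Fit the plate's standard curve and invert all sample/control wells.

    Duplicates are averaged after inversion to concentration, and a sample
    is flagged below the limit of detection if its mean concentration falls
    under the assay sensitivity.
    """
    std = plate[plate["role"] == "standard"]
    if std.empty:
        raise ValueError("plate has no standard wells")
    fit = fit_4pl(
        std["concentration_ngml"].to_numpy(float), std["response"].to_numpy(float)
    )
    if not fit.monotone_standards:
        logger.warning("plate standards are not monotone; fitting best 4PL anyway")

    def _invert_group(group: pd.DataFrame) -> pd.Series:
        conc, below = invert_4pl(fit.params, group["response"].to_numpy(float))
        conc = np.atleast_1d(conc)
        mean = float(conc.mean())
        cv = float(100.0 * conc.std(ddof=1) / mean) if conc.size > 1 and mean else np.nan
        return pd.Series(
            {
                "conc_ngml": mean,
                "duplicate_cv_percent": cv,
                "below_lod": bool(mean < LOD_NGML),
                "n_wells": int(conc.size),
            }
        )

    results = {}
    for role in ("sample", "control"):
        part = plate[plate["role"] == role]
        if part.empty:
            results[role] = pd.DataFrame(
                columns=["conc_ngml", "duplicate_cv_percent", "below_lod", "n_wells"]
            )
        else:
            results[role] = (
                part.groupby("sample_id", sort=True)
                .apply(_invert_group, include_groups=False)
                .astype({"n_wells": int})
            )
    flags = {"monotone_standards": fit.monotone_standards}
    return PlateResult(fit=fit, samples=results["sample"], controls=results["control"], flags=flags)
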