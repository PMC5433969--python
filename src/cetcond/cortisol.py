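"""Blubber cortisol inference chain.

From quantified ng/g concentrations: gamma log-link mixed models for body
site and blubber layer (repeated measures per individual), and the gamma
GLM covariate analysis (sex, age class, cause of death, mass/length^2) on
the dorsal outer-layer samples that stand in for remote biopsies.
Candidate models are compared by AICc through all-subsets selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import assay_cv, quantify_plate, to_tissue_concentration
from .gamma_glmm import GammaFitResult, fit_gamma_glm, fit_gamma_glmm
from .selection import SelectionTable, all_subsets_select

__all__ = [
    "quantify_samples",
    "fit_site_glmm",
    "fit_layer_glmm",
    "fit_covariate_glm",
    "marginal_factor_means",
    "layer_contrasts",
]

logger = logging.getLogger(__name__)


def quantify_samples(
    plates: Sequence[pd.DataFrame],
    sample_meta: pd.DataFrame,
    resuspension_volume_ml: float = 0.5,
) -> dict:
    """Run the plate quantification chain and join with tissue metadata.

    ``sample_meta`` must carry one row per sample id (as placed on the
    plates) with ``tissue_mass_g`` and ``efficiency`` columns.  Returns the
    quantified table (ng/ml and corrected ng/g), per-plate results, and the
    intra/inter CV quality gates.
    """
    per_sample, plate_results = [], []
    duplicates: dict[str, np.ndarray] = {}
    controls: dict[str, list] = {}
    for p_idx, plate in enumerate(plates):
        res = quantify_plate(plate)
        plate_results.append(res)
        for sid, row in res.samples.iterrows():
            per_sample.append(
                {
                    "sample_id": sid,
                    "plate": p_idx,
                    "conc_ngml": row["conc_ngml"],
                    "duplicate_cv_percent": row["duplicate_cv_percent"],
                    "below_lod": row["below_lod"],
                }
            )
        from .fourpl import invert_4pl

        dup_wells = plate[plate["role"] == "sample"]
        for sid, grp in dup_wells.groupby("sample_id"):
            conc, _ = invert_4pl(res.fit.params, grp["response"].to_numpy(float))
            duplicates[f"{p_idx}:{sid}"] = np.atleast_1d(conc)
        for cid, row in res.controls.iterrows():
            controls.setdefault(cid, []).append(row["conc_ngml"])
    quantified = pd.DataFrame(per_sample)
    cv = assay_cv(
        duplicates=duplicates or None,
        controls_by_plate={k: np.array(v) for k, v in controls.items()} or None,
    )
    meta = sample_meta.set_index("sample_id")
    quantified = quantified.join(meta, on="sample_id")
    quantified["concentration_ngg"] = to_tissue_concentration(
        quantified["conc_ngml"].to_numpy(float),
        quantified["tissue_mass_g"].to_numpy(float),
        quantified["efficiency"].to_numpy(float),
        resuspension_volume_ml=resuspension_volume_ml,
    )
    return {"samples": quantified, "plates": plate_results, "qc": cv}


def _glmm_selection(
    data: pd.DataFrame,
    candidates: Sequence[str],
    forced: Sequence[str] = (),
) -> SelectionTable:
    y = data["concentration_ngg"].to_numpy(float)

    def fitter(terms: tuple[str, ...]) -> GammaFitResult:
        return fit_gamma_glmm(
            y, data, tuple(forced) + terms, data["individual_id"].to_numpy()
        )

    return all_subsets_select(candidates, fitter, criterion="aicc")


def fit_site_glmm(
    full_depth: pd.DataFrame, select: bool = True
) -> tuple[GammaFitResult, SelectionTable | None]:
    """Body-site model for full-depth samples (gamma GLMM, random
    intercept per individual).

    Candidate fixed effects: site, condition (mass/length^2), and their
    interaction, selected by AICc.  Returns the AICc-best fit and the
    selection table; with ``select=False`` simply fits the site model (for
    marginal site means).
    """
    _check_repeated(full_depth)
    if not select:
        fit = fit_gamma_glmm(
            full_depth["concentration_ngg"].to_numpy(float),
            full_depth,
            ("site",),
            full_depth["individual_id"].to_numpy(),
        )
        return fit, None
    sel = _glmm_selection(full_depth, ("site", "quetelet", "site:quetelet"))
    return sel.best_fit, sel


def fit_layer_glmm(
    layer_samples: pd.DataFrame, select: bool = True
) -> tuple[GammaFitResult, SelectionTable | None]:
    """Body-site and blubber-layer model (gamma GLMM).

    Candidates: site, layer, condition, condition:site, condition:layer.
    """
    _check_repeated(layer_samples)
    if not select:
        fit = fit_gamma_glmm(
            layer_samples["concentration_ngg"].to_numpy(float),
            layer_samples,
            ("site", "layer"),
            layer_samples["individual_id"].to_numpy(),
        )
        return fit, None
    sel = _glmm_selection(
        layer_samples,
        ("site", "layer", "quetelet", "quetelet:site", "quetelet:layer"),
    )
    return sel.best_fit, sel


def fit_covariate_glm(
    outer_dorsal: pd.DataFrame,
    candidates: Sequence[str] = ("sex", "age_class", "cod_class", "quetelet"),
) -> tuple[GammaFitResult, SelectionTable]:
    """Covariate analysis of dorsal outer-layer cortisol (gamma GLM).

    All-subsets AICc selection over sex, age class, cause of death, and
    mass/length^2; one observation per individual, no random effect.
    """
    y = outer_dorsal["concentration_ngg"].to_numpy(float)
    n = len(outer_dorsal)
    if n < len(candidates) + 2:
        raise ValueError(f"n={n} too small for the covariate analysis")

    def fitter(terms: tuple[str, ...]) -> GammaFitResult:
        return fit_gamma_glm(y, outer_dorsal, terms)

    sel = all_subsets_select(candidates, fitter, criterion="aicc")
    return sel.best_fit, sel


def _check_repeated(data: pd.DataFrame) -> None:
    counts = data.groupby("individual_id").size()
    if (counts < 2).all():
        raise ValueError("need repeated measures per individual for a GLMM")


def marginal_factor_means(fit: GammaFitResult, data: pd.DataFrame, factor: str) -> pd.Series:
    """Population-averaged fitted means (ng/g) per level of a factor.

    Other model covariates are held at their observed values and averaged
    over the sample, which matches how group means are usually reported.
    """
    out = {}
    for level in pd.unique(data[factor]):
        counterfactual = data.copy()
        counterfactual[factor] = level
        out[level] = float(np.mean(fit.marginal_means(counterfactual)))
    return pd.Series(out, name=f"marginal_mean_{factor}")


def layer_contrasts(fit: GammaFitResult, reference: str = "outer") -> pd.DataFrame:
    """Pairwise blubber-layer contrasts vs the reference, log scale."""
    rows = []
    for col in fit.coef.index:
        if col.startswith("layer["):
            level = col[len("layer[") : -1]
            est, se = float(fit.coef[col]), float(fit.se[col])
            z = est / se if se > 0 else np.nan
            from scipy import stats

            rows.append(
                {
                    "contrast": f"{level} - {reference}",
                    "estimate_log": est,
                    "se": se,
                    "z": z,
                    "p_value": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
    return pd.DataFrame(rows)
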