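"""All-subsets information-criterion model selection with Akaike weights.

Mirrors what exhaustive "dredge"-style selection does: every subset of the
candidate terms that respects marginality (an interaction ``a:b`` enters
only when both ``a`` and ``b`` do) is fitted, ranked by AIC or AICc, and
assigned Akaike weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``.
Two leading models closer than 2 criterion points are flagged as being of
equivalent fit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectionTable",
    "enumerate_subsets",
    "akaike_weights",
    "equivalence_set_from_deltas",
    "all_subsets_select",
]

logger = logging.getLogger(__name__)

#: two models whose criterion values differ by less than this are treated
#: as statistically equivalent descriptions of the data
EQUIVALENCE_DELTA = 2.0


def _interaction_parts(term: str) -> list[str]:
    return term.split(":")


def enumerate_subsets(candidate_terms: Sequence[str]) -> list[tuple[str, ...]]:
    """All marginality-respecting subsets of the candidates (incl. empty).

    The result is sorted deterministically so selection is invariant to the
    order in which candidates are supplied.
    """
    mains = [t for t in candidate_terms if ":" not in t]
    inters = [t for t in candidate_terms if ":" in t]
    for term in inters:
        for part in _interaction_parts(term):
            if part not in mains:
                raise ValueError(
                    f"interaction {term!r} requires main effect {part!r} "
                    "among the candidates"
                )
    subsets: set[tuple[str, ...]] = set()
    order = {t: i for i, t in enumerate(sorted(candidate_terms))}
    for r in range(len(mains) + 1):
        for main_combo in itertools.combinations(sorted(mains), r):
            allowed = [
                t
                for t in inters
                if all(p in main_combo for p in _interaction_parts(t))
            ]
            for r2 in range(len(allowed) + 1):
                for int_combo in itertools.combinations(sorted(allowed), r2):
                    terms = tuple(
                        sorted(main_combo + int_combo, key=order.__getitem__)
                    )
                    subsets.add(terms)
    return sorted(subsets, key=lambda ts: (len(ts), ts))


def akaike_weights(criterion_values: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) normalized over the candidate set."""
    c = np.asarray(criterion_values, dtype=float)
    delta = c - np.nanmin(c)
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def equivalence_set_from_deltas(deltas: Sequence[float]) -> list[int]:
    """Indices (0-based, sorted order) of models equivalent to the best.

    Non-empty beyond the best model iff the runner-up is within
    ``EQUIVALENCE_DELTA`` of the leader.
    """
    d = np.asarray(deltas, dtype=float)
    return [int(i) for i in np.where(d < EQUIVALENCE_DELTA)[0]]


@dataclass
class SelectionTable:
    """Ranked candidate-model set from an all-subsets selection run."""

    frame: pd.DataFrame
    criterion: str
    best_terms: tuple[str, ...]
    equivalence: list[tuple[str, ...]]
    fits: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    @property
    def best_fit(self):
        return self.fits[self.best_terms]

    @property
    def is_equivalent_pair(self) -> bool:
        """True when the two best models are closer than 2 criterion points."""
        return len(self.equivalence) > 1

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def all_subsets_select(
    candidate_terms: Sequence[str],
    fitter: Callable[[tuple[str, ...]], object],
    criterion: str = "aicc",
) -> SelectionTable:
    """Fit every marginality-respecting subset and rank by the criterion.

    ``fitter(terms)`` must return an object exposing ``aic``, ``aicc`` and
    ``df_total`` attributes; models whose fit raises are excluded from the
    weights and recorded in ``failures``.
    """
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    rows, fits, failures = [], {}, []
    for terms in enumerate_subsets(candidate_terms):
        try:
            fit = fitter(terms)
        except Exception as exc:  # noqa: BLE001 - candidate failure is data-driven
            logger.warning("candidate model %s failed to fit: %s", terms, exc)
            failures.append((terms, str(exc)))
            continue
        rows.append(
            {
                "model_terms": terms,
                "model": " + ".join(terms) if terms else "1",
                "df": getattr(fit, "df_total"),
                criterion: getattr(fit, criterion),
            }
        )
        fits[terms] = fit
    if not rows:
        raise RuntimeError("no candidate model could be fitted")
    frame = pd.DataFrame(rows).sort_values(criterion, kind="mergesort").reset_index(drop=True)
    frame["delta"] = frame[criterion] - frame[criterion].iloc[0]
    frame["weight"] = akaike_weights(frame[criterion].to_numpy())
    eq_idx = equivalence_set_from_deltas(frame["delta"].to_numpy())
    equivalence = [tuple(frame.loc[i, "model_terms"]) for i in eq_idx]
    return SelectionTable(
        frame=frame,
        criterion=criterion,
        best_terms=tuple(frame.loc[0, "model_terms"]),
        equivalence=equivalence,
        fits=fits,
        failures=failures,
    )
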