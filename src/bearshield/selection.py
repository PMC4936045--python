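"""Candidate model set, AICc ranking, and interaction importance.

Fifteen biologically motivated candidate models combine three covariate
themes — anthropogenic (distances to habitation, road, forest road),
land cover (the six dummy-coded classes) and vegetation (NDVI) — each
with or without litter-survival interactions, from the full model down to
the intercept-plus-random-effects null.  Models are ranked by AICc with
Akaike weights; models at delta AICc >= 4 from the best are flagged
inconclusive.

The importance of each survival interaction in the best model is measured
by systematic exclusion: delta_AICc_diff = AICc(full) - AICc(full without
that one interaction, main effect kept).  Negative values support keeping
the interaction; for reporting the sign is reversed so larger = more
important, with the >= 4 threshold marking a conclusive contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import FitResult, ModelSpec, akaike_weights, fit_model
from .landscape import DISTANCE_LAYERS, LANDCOVER_INDICATORS
from .design import interaction_col

__all__ = [
    "CandidateSet",
    "CONCLUSIVE_DELTA",
    "build_candidate_set",
    "rank_models",
    "interaction_importance",
]

CONCLUSIVE_DELTA = 4.0

ANTHROPOGENIC = DISTANCE_LAYERS
LAND_COVER = LANDCOVER_INDICATORS
VEGETATION = ("ndvi",)


@dataclass(frozen=True)
class CandidateSet:
    specs: tuple[ModelSpec, ...]

    def __post_init__(self) -> None:
        keys = {
            (s.fixed_terms, s.interaction_terms, s.survival_main, s.random_factors)
            for s in self.specs
        }
        if len(keys) != len(self.specs):
            raise ValueError("candidate set contains duplicate model specifications")

    def labels(self) -> list[str]:
        return [s.label for s in self.specs]


def build_candidate_set(
    all_terms=ANTHROPOGENIC + LAND_COVER + VEGETATION,
    vif: dict[str, float] | None = None,
    vif_threshold: float = 3.0,
    random_factors=("bear_id", "year"),
    specs: tuple[ModelSpec, ...] | None = None,
) -> CandidateSet:
    """The default 15-model candidate set (overridable via ``specs``).

    If a VIF report is supplied, terms at or above ``vif_threshold`` are
    screened out of every candidate before the set is built.
    """
    if specs is not None:
        return CandidateSet(specs=tuple(specs))
    if vif is not None:
        dropped = {t for t, v in vif.items() if v >= vif_threshold}
        all_terms = tuple(t for t in all_terms if t not in dropped)
    keep = lambda group: tuple(t for t in group if t in all_terms)  # noqa: E731
    anth, lc, veg = keep(ANTHROPOGENIC), keep(LAND_COVER), keep(VEGETATION)
    full = tuple(all_terms)

    def spec(label, fixed, inter=()):
        return ModelSpec(
            label=label,
            fixed_terms=tuple(fixed),
            interaction_terms=tuple(inter),
            random_factors=tuple(random_factors),
        )

    candidates = (
        spec("full + all interactions", full, full),
        spec("full + anthropogenic interactions", full, anth),
        spec("full + land-cover interactions", full, lc),
        spec("full, no interactions", full),
        spec("anthropogenic + interactions", anth, anth),
        spec("anthropogenic", anth),
        spec("land cover + interactions", lc, lc),
        spec("land cover", lc),
        spec("vegetation + interaction", veg, veg),
        spec("vegetation", veg),
        spec("anthropogenic + vegetation + interactions", anth + veg, anth + veg),
        spec("anthropogenic + vegetation", anth + veg),
        spec("land cover + vegetation + interactions", lc + veg, lc + veg),
        spec("land cover + vegetation", lc + veg),
        spec("null (random intercepts only)", ()),
    )
    return CandidateSet(specs=candidates)


def rank_models(
    table: pd.DataFrame, candidates: CandidateSet, **fit_kwargs
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit every candidate and rank by AICc.

    Returns the selection table (sorted ascending by AICc, with delta and
    Akaike weights over the successfully fitted models) and the fits by
    label.  Individual fit failures are logged in the table with their
    error and excluded from the ranking; if every fit fails, raises.
    """
    rows = []
    fits: dict[str, FitResult] = {}
    failures: list[tuple[str, str]] = []
    for spec in candidates.specs:
        try:
            fit = fit_model(table, spec, **fit_kwargs)
        except Exception as err:  # fit failures never abort the ranking
            failures.append((spec.label, str(err)))
            continue
        fits[spec.label] = fit
        rows.append((spec.label, fit.k, fit.loglik, fit.aicc))
    if not rows:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    tab = pd.DataFrame(rows, columns=["label", "k", "loglik", "aicc"])
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    tab["weight"] = akaike_weights(tab["aicc"])
    tab["conclusive"] = tab["delta_aicc"] < CONCLUSIVE_DELTA
    tab = tab.sort_values("aicc", kind="stable").reset_index(drop=True)
    for label, err in failures:
        tab.loc[len(tab)] = [label, np.nan, np.nan, np.nan, np.nan, np.nan, False]
        tab.loc[len(tab) - 1, "label"] = f"{label} [fit failed: {err}]"
    return tab, fits


def interaction_importance(
    table: pd.DataFrame,
    best_fit: FitResult,
    **fit_kwargs,
) -> pd.DataFrame:
    """Per-interaction importance by systematic exclusion from the best model.

    For each survival interaction j in the best model, the model is refitted
    without j (keeping j's main effect) and
    ``delta_aicc_diff = AICc(best) - AICc(reduced)`` recorded; the reported
    importance is its negation, sorted descending, with the conclusiveness
    flag at the >= 4 threshold.  Reduced-model fit failures flag the term
    ``not evaluable`` instead of aborting.
    """
    spec = best_fit.spec
    if not spec.interaction_terms:
        raise ValueError("best model contains no survival interactions")
    rows = []
    for term in spec.interaction_terms:
        col = interaction_col(term)
        est = best_fit.beta[col]
        se = best_fit.se[col]
        try:
            reduced = fit_model(table, spec.without_interaction(term), **fit_kwargs)
            diff = best_fit.aicc - reduced.aicc
            rows.append((term, est, se, diff, -diff, -diff >= CONCLUSIVE_DELTA, ""))
        except Exception as err:
            rows.append((term, est, se, np.nan, np.nan, False, f"not evaluable: {err}"))
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "estimate",
            "se",
            "delta_aicc_diff",
            "reported_importance",
            "conclusive",
            "note",
        ],
    )
    return out.sort_values("reported_importance", ascending=False, kind="stable").reset_index(
        drop=True
    )
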