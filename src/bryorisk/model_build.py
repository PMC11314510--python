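"""Maximal-model construction and forward stepwise AIC selection.

Two maximal models are built from the screening results.  Model 1 takes the
significant traits that are not sporophyte morphology, plus the binary
"Sporophyte presence" trait, so it applies to every species.  Model 2 takes
all significant traits except "Sporophyte presence" (it only applies to
sporophyte-bearing species with recorded morphology) and drops any trait
excluded for trait–trait correlation (seta shape, which tracks seta length).

Each maximal model is then reduced by forward stepwise selection: starting
from the intercept-only fit, the candidate whose addition lowers the AIC
the most is added, until no addition improves the AIC.  The survivor is the
minimum adequate model (MAM).  Complete cases are recomputed per model, so
the two models legitimately use different subsets (and different z-scaling
moments) of the same matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .registry import SPOROPHYTE_MORPHOLOGY_TRAITS, TRAIT_NAMES
from .screening import PairAssociation, ScreenResult, encode_trait
from .trait_matrix import ScalingParams, TraitMatrix


@dataclass
class ModelSpec:
    """Candidate predictor set for one maximal model."""

    model_id: str  # "M1" or "M2"
    candidate_predictors: list[str]
    forced_exclusions: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class MAMResult:
    """A selected minimum adequate model with its AIC trace."""

    model_id: str
    selected_predictors: list[str]
    fit: glm.GLMFit
    trace: list[tuple[int, str | None, float]]  # (step, added candidate, AIC)
    scaling: dict[str, ScalingParams]
    n_complete: int
    n_threatened: int
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _registry_order(names) -> list[str]:
    return [t for t in TRAIT_NAMES if t in set(names)]


def build_maximal_models(
    screen: list[ScreenResult], pair_results: list[PairAssociation]
) -> tuple[ModelSpec, ModelSpec]:
    """Derive the two maximal-model candidate sets from the screens.

    Correlated pairs where both members are significant contribute an
    exclusion: the later-registry member (seta shape, for the seta pair) is
    dropped from model 2's candidates with the reason recorded.
    """
    significant = [r.trait for r in screen if r.significant]
    if not significant:
        import logging

        logging.getLogger(__name__).warning(
            "no significant traits: both maximal models are intercept-only"
        )
    sig = set(significant)
    morph = set(SPOROPHYTE_MORPHOLOGY_TRAITS)

    m1 = _registry_order((sig - morph) | ({"Sporophyte presence"} if sig else set()))
    m1_spec = ModelSpec("M1", m1, [(t, "sporophyte morphology") for t in sorted(sig & morph)])

    exclusions: list[tuple[str, str]] = [("Sporophyte presence", "model 2 is morphology-based")]
    excluded = {"Sporophyte presence"}
    for pr in pair_results:
        if pr.p_value < 0.05 and pr.trait_a in sig and pr.trait_b in sig:
            # drop the later-registry member of a dependent significant pair
            later = max((pr.trait_a, pr.trait_b), key=TRAIT_NAMES.index)
            if later not in excluded:
                exclusions.append((later, f"correlated with {min((pr.trait_a, pr.trait_b), key=TRAIT_NAMES.index)}"))
                excluded.add(later)
    m2 = _registry_order(sig - excluded)
    return m1_spec, ModelSpec("M2", m2, exclusions)


def build_design(
    matrix: TraitMatrix, traits: list[str], rows: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, ScalingParams]]:
    """Encode the given traits over ``rows`` into a numeric design.

    Continuous traits are z-scaled with moments from ``rows`` (sample SD)
    unless the matrix already carries scaling for them; the scaling used is
    returned so fitted coefficients can be applied to raw-unit inputs.
    """
    cols: dict[str, pd.Series] = {}
    scaling: dict[str, ScalingParams] = {}
    for name in traits:
        tdef = matrix.definition(name)
        series = encode_trait(rows[name], tdef)
        if tdef.kind == "continuous":
            if name in matrix.scaling:
                scaling[name] = matrix.scaling[name]
            else:
                params = ScalingParams(
                    mean=float(series.mean()), sd=float(series.std(ddof=1))
                )
                series = pd.Series(params.transform(series), index=series.index)
                scaling[name] = params
        cols[name] = series
    return pd.DataFrame(cols), scaling


def stepwise_forward_aic(spec: ModelSpec, matrix: TraitMatrix) -> MAMResult:
    """Greedy forward AIC selection over the spec's candidates.

    The complete-case subset (non-DD rows with every candidate observed) is
    fixed up front so AIC values are comparable across steps.  Ties are
    broken by candidate order in the spec; a candidate whose fit separates
    is skipped with a warning rather than aborting the search.
    """
    rows = matrix.non_dd()
    cols = [c for c in spec.candidate_predictors if c in rows.columns]
    complete = rows[cols + ["threat_status"]].dropna() if cols else rows[["threat_status"]]
    y = complete["threat_status"].astype(float)
    if y.nunique() < 2:
        raise ValueError("complete-case subset lacks both outcome classes")

    design, scaling = build_design(matrix, cols, complete)

    current: list[str] = []
    current_fit = glm.fit_logistic(y, None)
    trace: list[tuple[int, str | None, float]] = [(0, None, current_fit.aic)]
    skipped: list[tuple[str, str]] = []
    step = 0
    remaining = list(cols)
    while remaining:
        best_name, best_fit = None, None
        for name in remaining:  # spec order ⇒ deterministic tie-break
            try:
                fit = glm.fit_logistic(y, design[current + [name]])
            except (glm.SeparationError, glm.ConvergenceError, ValueError) as exc:
                skipped.append((name, str(exc)))
                remaining = [r for r in remaining if r != name]
                continue
            if best_fit is None or fit.aic < best_fit.aic - 1e-12:
                best_name, best_fit = name, fit
        if best_fit is None or best_fit.aic >= current_fit.aic:
            break
        step += 1
        current.append(best_name)
        remaining.remove(best_name)
        current_fit = best_fit
        trace.append((step, best_name, best_fit.aic))

    return MAMResult(
        model_id=spec.model_id,
        selected_predictors=list(current),
        fit=current_fit,
        trace=trace,
        scaling={k: v for k, v in scaling.items() if k in current},
        n_complete=len(complete),
        n_threatened=int((y == 1).sum()),
        skipped=skipped,
    )


def predict_mam(mam: MAMResult, matrix: TraitMatrix, rows: pd.DataFrame | None = None) -> pd.Series:
    """Risk probabilities for arbitrary rows under a fitted MAM.

    Continuous predictors are standardised with the scaling stored on the
    MAM (its own complete-case moments); rows missing any selected
    predictor get NaN, never zero.
    """
    rows = matrix.data if rows is None else rows
    eta = pd.Series(mam.fit.coef("Intercept"), index=rows.index, dtype=float)
    for name in mam.selected_predictors:
        tdef = matrix.definition(name)
        x = encode_trait(rows[name], tdef)
        if tdef.kind == "continuous" and name in mam.scaling:
            x = pd.Series(mam.scaling[name].transform(x), index=rows.index)
        eta = eta + mam.fit.coef(name) * x
    return 1.0 / (1.0 + np.exp(-eta))


def exhaustive_best_aic(spec: ModelSpec, matrix: TraitMatrix) -> float:
    """Minimum AIC over all candidate subsets (test oracle, exponential)."""
    from itertools import combinations

    rows = matrix.non_dd()
    cols = [c for c in spec.candidate_predictors if c in rows.columns]
    complete = rows[cols + ["threat_status"]].dropna() if cols else rows[["threat_status"]]
    y = complete["threat_status"].astype(float)
    design, _ = build_design(matrix, cols, complete)
    best = np.inf
    for k in range(len(cols) + 1):
        for subset in combinations(cols, k):
            try:
                fit = glm.fit_logistic(y, design[list(subset)] if subset else None)
            except (glm.SeparationError, glm.ConvergenceError, ValueError):
                continue
            best = min(best, fit.aic)
    return float(best)
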