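"""Univariate trait screening and trait–trait association checks.

Each trait is screened with its own logistic regression of binary threat
status on that trait alone (continuous traits entered as z-scores, binary
and two-level categorical traits as 0/1 indicators against the registry
reference level).  Trait pairs suspected of dependence are screened with a
Pearson chi-square (binary × binary) or a logistic fit of the binary trait
on the log of the continuous one (binary × continuous).  No multiplicity
correction is applied across the fifteen screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm
from .registry import BINARY_LEVELS, TraitDefinition
from .trait_matrix import TraitMatrix

DEFAULT_ALPHA = 0.05

#: Trait pairs the analysis checks for dependence before model building.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("Plant sex", "Vegetative reproduction"),
    ("Plant sex", "Sporophyte presence"),
    ("Seta length", "Seta shape"),
)


def encode_trait(series: pd.Series, tdef: TraitDefinition) -> pd.Series:
    """Numeric encoding of one trait column (NaN preserved).

    Binary: present=1/absent=0.  Categorical: indicator of the non-reference
    attribute (first registry attribute is the reference).  Continuous:
    values as float (caller decides about z-scaling).
    """
    if tdef.kind == "continuous":
        return series.astype(float)
    levels = BINARY_LEVELS if tdef.kind == "binary" else tdef.attributes
    mapping = {lev: float(i) for i, lev in enumerate(levels)}
    return series.map(lambda v: mapping.get(v, np.nan) if v is not None else np.nan)


def contrast_label(tdef: TraitDefinition) -> str:
    if tdef.kind == "binary":
        return "present"
    if tdef.kind == "categorical":
        return tdef.attributes[1]
    return "per SD"


@dataclass
class ScreenResult:
    """Result of one univariate threat ~ trait logistic screen."""

    trait: str
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    n_used: int
    alpha: float
    estimable: bool = True
    note: str = ""


def _zscores(matrix: TraitMatrix, trait: str, subset: pd.DataFrame) -> pd.Series:
    values = subset[trait].astype(float)
    if trait in matrix.scaling:  # already z-scaled
        return values
    sd = values.std(ddof=1)
    if not sd > 0 or not np.isfinite(sd):
        raise ValueError(f"degenerate continuous trait {trait!r}")
    return (values - values.mean()) / sd


def screen_traits(matrix: TraitMatrix, alpha: float = DEFAULT_ALPHA) -> list[ScreenResult]:
    """One logistic fit per registry trait; DD species excluded.

    Traits with a single observed level (or that separate the outcome) are
    returned flagged not-estimable rather than dropped, so the result list
    always covers the registry in canonical order.
    """
    rows = matrix.non_dd()
    y = rows["threat_status"].astype(float)
    results: list[ScreenResult] = []
    for tdef in matrix.definitions:
        name = tdef.name
        if name not in rows.columns:
            continue
        sub = rows[[name]].join(y.rename("y")).dropna()
        label = contrast_label(tdef)

        def not_estimable(note: str) -> ScreenResult:
            return ScreenResult(
                trait=name, contrast=label, estimate=np.nan, ci_low=np.nan,
                ci_high=np.nan, p_value=np.nan, significant=False,
                n_used=len(sub), alpha=alpha, estimable=False, note=note,
            )

        try:
            if tdef.kind == "continuous":
                x = _zscores(matrix, name, sub)
            else:
                x = encode_trait(sub[name], tdef)
                if x.dropna().nunique() < 2:
                    results.append(not_estimable("single observed level"))
                    continue
            fit = glm.fit_logistic(sub["y"], pd.DataFrame({name: x}))
        except (ValueError, glm.SeparationError, glm.ConvergenceError) as exc:
            results.append(not_estimable(str(exc)))
            continue

        est = fit.coefficients[1]
        half = glm.wald_ci(fit, 0.95)[1]
        p = float(fit.p_values[1])
        results.append(
            ScreenResult(
                trait=name, contrast=label, estimate=float(est),
                ci_low=float(est - half), ci_high=float(est + half),
                p_value=p, significant=bool(p < alpha), n_used=fit.n, alpha=alpha,
            )
        )
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("trait")


@dataclass
class PairAssociation:
    """Association between two traits (dependence screen)."""

    trait_a: str
    trait_b: str
    method: str  # "chisq" or "logit_log"
    statistic: float
    p_value: float
    direction: float  # log odds ratio (chisq) or slope sign carrier (logit)


def screen_trait_pairs(
    matrix: TraitMatrix, pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
) -> list[PairAssociation]:
    """Dependence screen for the given trait pairs.

    (binary, binary): Pearson chi-square on the 2×2 table, direction = log
    odds ratio.  (continuous, binary): logistic fit of the binary trait on
    the natural log of the continuous one, direction = fitted slope.
    """
    rows = matrix.data
    out: list[PairAssociation] = []
    for a, b in pairs:
        da, db = matrix.definition(a), matrix.definition(b)
        # orient so a continuous member comes first
        if db.kind == "continuous":
            a, b, da, db = b, a, db, da
        if da.kind == "continuous":
            sub = rows[[a, b]].dropna()
            x = sub[a].astype(float)
            if (x <= 0).any():
                raise ValueError(f"non-positive {a!r} values under log transform")
            yb = encode_trait(sub[b], db)
            fit = glm.fit_logistic(yb, pd.DataFrame({f"log_{a}": np.log(x)}))
            slope = float(fit.coefficients[1])
            out.append(
                PairAssociation(a, b, "logit_log", float(fit.z_values[1]),
                                float(fit.p_values[1]), slope)
            )
        else:
            sub = rows[[a, b]].dropna()
            xa, xb = encode_trait(sub[a], da), encode_trait(sub[b], db)
            test = glm.chisq_association(xa, xb)
            out.append(
                PairAssociation(a, b, "chisq", test.statistic, test.p_value,
                                float(np.log(test.odds_ratio)))
            )
    return out
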