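"""Risk scoring with the published models and Data Deficient triage.

The two published minimum adequate models are kept as versioned parameter
records so raw-unit trait values can be scored without refitting:

MAM1 (all species)::

    logit(risk) = −0.79 + 0.54·[monoicous] − 1.18·[sporophyte present]
                  − 0.83·(substrate breadth − 1.69)/0.94          cutoff 0.21

MAM2 (sporophyte-bearing species with recorded morphology)::

    logit(risk) = −1.65 − 0.61·(seta length − 14)/13.32
                  − 0.90·(substrate breadth − 1.8)/0.98           cutoff 0.18

Classification is ``risk >= cutoff ⇒ threatened``.  A species scored by
both models gets the verdict *Threatened* when both agree threatened,
*Non-threatened* when both agree non-threatened, and *Possibly Threatened*
when they disagree; with a single available model its class is the verdict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .trait_matrix import ScalingParams, TraitMatrix

VERDICT_THREATENED = "Threatened"
VERDICT_POSSIBLY = "Possibly Threatened"
VERDICT_NON_THREATENED = "Non-threatened"
VERDICTS = (VERDICT_THREATENED, VERDICT_POSSIBLY, VERDICT_NON_THREATENED)


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class RiskModelParams:
    """Parameters of one risk model on the raw-unit scale."""

    model_id: str
    intercept: float
    coefficients: dict[str, float]  # per level (binary) / per SD (continuous)
    scaling: dict[str, ScalingParams]
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "scaling": {k: [v.mean, v.sd] for k, v in self.scaling.items()},
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModelParams":
        return cls(
            model_id=d["model_id"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            scaling={k: ScalingParams(*map(float, v)) for k, v in d["scaling"].items()},
            cutoff=float(d["cutoff"]),
        )


def _load_published() -> dict[str, RiskModelParams]:
    text = resources.files("bryorisk.data").joinpath("published_models.json").read_text()
    return {k: RiskModelParams.from_dict(v) for k, v in json.loads(text).items()}


_PUBLISHED = _load_published()
PUBLISHED_MAM1: RiskModelParams = _PUBLISHED["MAM1"]
PUBLISHED_MAM2: RiskModelParams = _PUBLISHED["MAM2"]


def score_mam1(
    sex: str,
    sporophyte: str,
    substrate_breadth: float,
    params: RiskModelParams = PUBLISHED_MAM1,
) -> float:
    """Probability of being threatened under the all-species model.

    ``sex`` is "dioicous" or "monoicous"; ``sporophyte`` is "absent" or
    "present"; breadth is the raw substrate count (>= 1).  Any missing input
    yields NaN, never zero.
    """
    if params.model_id != "MAM1":
        raise ValueError("params are not a MAM1 record")
    if sex is None or sporophyte is None or _missing(substrate_breadth):
        return math.nan
    if sex not in ("dioicous", "monoicous"):
        raise ValueError(f"sex must be dioicous/monoicous, got {sex!r}")
    if sporophyte not in ("absent", "present"):
        raise ValueError(f"sporophyte must be absent/present, got {sporophyte!r}")
    eta = (
        params.intercept
        + params.coefficients["Plant sex"] * (sex == "monoicous")
        + params.coefficients["Sporophyte presence"] * (sporophyte == "present")
        + params.coefficients["Substrate breadth"]
        * float(params.scaling["Substrate breadth"].transform(substrate_breadth))
    )
    return _invlogit(eta)


def score_mam2(
    seta_length_mm: float,
    substrate_breadth: float,
    params: RiskModelParams = PUBLISHED_MAM2,
) -> float:
    """Probability of being threatened under the sporophyte-morphology model."""
    if params.model_id != "MAM2":
        raise ValueError("params are not a MAM2 record")
    if _missing(seta_length_mm) or _missing(substrate_breadth):
        return math.nan
    if seta_length_mm < 0:
        raise ValueError("seta length must be >= 0")
    eta = (
        params.intercept
        + params.coefficients["Seta length"]
        * float(params.scaling["Seta length"].transform(seta_length_mm))
        + params.coefficients["Substrate breadth"]
        * float(params.scaling["Substrate breadth"].transform(substrate_breadth))
    )
    return _invlogit(eta)


def _missing(x) -> bool:
    try:
        return x is None or math.isnan(float(x))
    except (TypeError, ValueError):
        return True


def classify(risk: float, cutoff: float) -> str | None:
    """Cutoff rule: risk >= cutoff ⇒ threatened (boundary inclusive)."""
    if _missing(risk):
        return None
    if not (0 <= risk <= 1 and 0 <= cutoff <= 1):
        raise ValueError("risk and cutoff must lie in [0, 1]")
    return "threatened" if risk >= cutoff else "non-threatened"


def verdict(class_mam1: str | None, class_mam2: str | None) -> str:
    """Combine the per-model classes into a triage verdict."""
    classes = [c for c in (class_mam1, class_mam2) if c is not None]
    if not classes:
        raise ValueError("at least one model class is required")
    if all(c == "threatened" for c in classes):
        return VERDICT_THREATENED
    if all(c == "non-threatened" for c in classes):
        return VERDICT_NON_THREATENED
    return VERDICT_POSSIBLY


@dataclass
class SpeciesRisk:
    species_name: str
    risk_mam1: float
    risk_mam2: float
    class_mam1: str | None
    class_mam2: str | None
    verdict: str


@dataclass
class TriageReport:
    """Per-species risks plus aggregate verdict counts."""

    species: list[SpeciesRisk]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def counts(self) -> dict[str, int]:
        c = {v: 0 for v in VERDICTS}
        for s in self.species:
            c[s.verdict] += 1
        return c

    def percentages(self) -> dict[str, float]:
        n = self.n_species
        return {k: 100.0 * v / n for k, v in self.counts().items()} if n else {}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.species]).set_index("species_name")


def triage_scores(
    scores: pd.DataFrame,
    params1: RiskModelParams = PUBLISHED_MAM1,
    params2: RiskModelParams = PUBLISHED_MAM2,
) -> TriageReport:
    """Triage from precomputed risk scores.

    ``scores`` needs columns ``risk_mam1`` and ``risk_mam2`` (NaN = model
    not available), indexed by species.  Only classification and the verdict
    rule are applied — this is the path used for the packaged fixture, whose
    printed risks are taken verbatim.
    """
    species: list[SpeciesRisk] = []
    excluded: list[str] = []
    for name, row in scores.iterrows():
        r1, r2 = float(row["risk_mam1"]), float(row["risk_mam2"])
        c1, c2 = classify(r1, params1.cutoff), classify(r2, params2.cutoff)
        if c1 is None and c2 is None:
            excluded.append(str(name))
            continue
        species.append(SpeciesRisk(str(name), r1, r2, c1, c2, verdict(c1, c2)))
    return TriageReport(species=species, excluded=excluded)


def score_matrix(
    matrix: TraitMatrix,
    params1: RiskModelParams = PUBLISHED_MAM1,
    params2: RiskModelParams = PUBLISHED_MAM2,
    *,
    dd_only: bool = False,
) -> pd.DataFrame:
    """Score every (or every DD) species of a raw-unit trait matrix.

    MAM1 applies whenever sex, sporophyte presence and substrate breadth are
    recorded; MAM2 additionally requires a recorded seta length.  Returns a
    frame with risk_mam1/risk_mam2 columns ready for :func:`triage_scores`.
    """
    if matrix.scaling:
        raise ValueError("score_matrix expects raw-unit (unscaled) trait values")
    rows = matrix.dd() if dd_only else matrix.data
    out = {}
    for name, row in rows.iterrows():
        r1 = score_mam1(
            row.get("Plant sex"), row.get("Sporophyte presence"),
            row.get("Substrate breadth"), params1,
        )
        r2 = score_mam2(row.get("Seta length"), row.get("Substrate breadth"), params2)
        out[name] = (r1, r2)
    return pd.DataFrame.from_dict(
        out, orient="index", columns=["risk_mam1", "risk_mam2"]
    ).rename_axis("species")


def load_dd_fixture() -> pd.DataFrame:
    """The packaged 44-species Data Deficient table (printed risk scores).

    Columns: ``risk_mam1``, ``risk_mam2`` (NaN where a model was not
    applicable) and the published ``reported_verdict``.
    """
    path = resources.files("bryorisk.data").joinpath("dd_species_scores.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, index_col="species")


def triage_dd_fixture(
    params1: RiskModelParams = PUBLISHED_MAM1,
    params2: RiskModelParams = PUBLISHED_MAM2,
) -> TriageReport:
    """Run classification + verdicts over the packaged DD table."""
    return triage_scores(load_dd_fixture(), params1, params2)
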