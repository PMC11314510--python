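"""Species × functional-trait matrix: data model, CSV I/O and preprocessing.

The matrix is the single input object of the pipeline.  One row per species,
one column per trait, plus the IUCN Red List category.  Preprocessing
implements the analysis's data rules:

* status binarisation — EX/CR/EN/VU are *threatened* (1), NT/LC are
  *non-threatened* (0), DD species are held out of model fitting but kept
  for triage;
* substrate breadth — the count of distinct substrate types a species has
  been recorded on, equally weighted;
* empty binary cells mean *absent* (taxonomic descriptions only mention
  structures that are present);
* continuous traits are z-scaled, with the scaling parameters retained so
  raw-unit inputs can be scored later.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import (
    CANONICAL_TRAITS,
    PRESENCE_TYPE_TRAITS,
    SPOROPHYTE_MORPHOLOGY_TRAITS,
    TraitDefinition,
)

logger = logging.getLogger(__name__)

IUCN_CATEGORIES = ("EX", "CR", "EN", "VU", "NT", "LC", "DD")
THREATENED_CATEGORIES = frozenset({"EX", "CR", "EN", "VU"})
NON_THREATENED_CATEGORIES = frozenset({"NT", "LC"})

DD = "DD"

_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–—]\s*(\d+(?:\.\d+)?)\s*$")


class TraitMatrixError(ValueError):
    """Malformed input to the trait-matrix layer."""


@dataclass(frozen=True)
class ScalingParams:
    """Mean and standard deviation used to z-scale a continuous trait.

    ``z = (x - mean) / sd``; the mean maps to z = 0.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise TraitMatrixError(f"scaling sd must be > 0, got {self.sd}")

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


@dataclass
class TraitMatrix:
    """Species × trait table with status labels and scaling state.

    Attributes
    ----------
    data : pandas.DataFrame
        Indexed by species name; columns ``iucn_category``, ``threat_status``
        (nullable Int64: 1 threatened, 0 non-threatened, NA for DD) and one
        column per trait.
    definitions : list of TraitDefinition
    scaling : dict
        Maps continuous trait name -> ScalingParams once the trait has been
        z-scaled; empty for raw matrices.
    log : list of str
        Parse/imputation log lines.
    """

    data: pd.DataFrame
    definitions: list[TraitDefinition] = field(
        default_factory=lambda: list(CANONICAL_TRAITS)
    )
    scaling: dict[str, ScalingParams] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------ #

    @property
    def n_species(self) -> int:
        return len(self.data)

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.definitions]

    def definition(self, name: str) -> TraitDefinition:
        for t in self.definitions:
            if t.name == name:
                return t
        raise KeyError(name)

    def status_counts(self) -> dict[str, int]:
        """Counts of threatened / non-threatened / DD records (sum = n)."""
        s = self.data["threat_status"]
        return {
            "threatened": int((s == 1).sum()),
            "non_threatened": int((s == 0).sum()),
            "dd": int(s.isna().sum()),
        }

    def non_dd(self) -> pd.DataFrame:
        """Rows eligible for model fitting (threat_status is 0 or 1)."""
        return self.data[self.data["threat_status"].notna()]

    def dd(self) -> pd.DataFrame:
        return self.data[self.data["threat_status"].isna()]

    def has_sporophyte_traits(self) -> pd.Series:
        """Per species: any sporophyte-morphology trait recorded."""
        cols = [c for c in SPOROPHYTE_MORPHOLOGY_TRAITS if c in self.data.columns]
        return self.data[cols].notna().any(axis=1)

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            data=self.data.copy(),
            definitions=list(self.definitions),
            scaling=dict(self.scaling),
            log=list(self.log),
        )


# ---------------------------------------------------------------------- #
# status binarisation


def binarize_status(category: str):
    """Map an IUCN category to a binary threat label.

    EX/CR/EN/VU -> 1 (threatened); NT/LC -> 0 (non-threatened); DD -> "DD"
    (held out of fitting, retained for triage).
    """
    if category in THREATENED_CATEGORIES:
        return 1
    if category in NON_THREATENED_CATEGORIES:
        return 0
    if category == DD:
        return DD
    raise TraitMatrixError(f"unrecognized IUCN category: {category!r}")


# ---------------------------------------------------------------------- #
# substrate breadth


def derive_substrate_breadth(substrates) -> float:
    """Count distinct substrate labels (equal weighting).

    An empty list yields a missing value (NaN), never zero: a species with
    no recorded substrate has unknown breadth, not breadth zero.
    """
    labels = {str(s).strip().lower() for s in substrates if str(s).strip()}
    if not labels:
        logger.warning("empty substrate list -> missing breadth")
        return math.nan
    return float(len(labels))


# ---------------------------------------------------------------------- #
# CSV reading


def _parse_continuous(cell: str, *, where: str, log: list[str]) -> float:
    m = _RANGE_RE.match(cell)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        value = (lo + hi) / 2.0
        log.append(f"{where}: range '{cell}' -> midpoint {value}")
        return value
    try:
        value = float(cell)
    except ValueError as exc:
        raise TraitMatrixError(f"{where}: cannot parse continuous value {cell!r}") from exc
    if value < 0:
        raise TraitMatrixError(f"{where}: negative measurement {value}")
    return value


def _parse_binary(cell: str, *, where: str) -> str:
    label = cell.strip().lower()
    if label in ("present", "absent"):
        return label
    if label in ("1", "yes", "true"):
        return "present"
    if label in ("0", "no", "false"):
        return "absent"
    raise TraitMatrixError(f"{where}: binary cell must be present/absent, got {cell!r}")


def read_trait_matrix(
    path,
    registry: tuple[TraitDefinition, ...] = CANONICAL_TRAITS,
    *,
    strict_columns: bool = False,
) -> TraitMatrix:
    """Read a species × trait CSV into a :class:`TraitMatrix`.

    The file must have columns ``species`` and ``iucn_category`` followed by
    trait columns matching the registry.  A ``Substrate breadth`` column may
    hold either a count or a ``|``-separated substrate list, from which the
    breadth is derived.  Empty cells ("") are missing; binary missing cells
    are *not* imputed here (see :func:`impute_binary_absence`).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"species", "iucn_category"}
    if not required.issubset(raw.columns):
        raise TraitMatrixError(f"CSV must have columns {sorted(required)}")

    known = {t.name for t in registry}
    unknown = [c for c in raw.columns if c not in known | required]
    log: list[str] = []
    if unknown:
        msg = f"unknown columns ignored: {unknown}"
        if strict_columns:
            raise TraitMatrixError(msg)
        logger.warning(msg)
        log.append(msg)

    if raw["species"].duplicated().any():
        dupes = raw.loc[raw["species"].duplicated(), "species"].tolist()
        raise TraitMatrixError(f"duplicate species names: {dupes}")

    records: dict[str, list] = {t.name: [] for t in registry}
    statuses: list = []
    for i, row in raw.iterrows():
        where_row = f"row {i + 2}"  # 1-based with header
        cat = row["iucn_category"].strip()
        statuses.append(binarize_status(cat))
        for t in registry:
            cell = row.get(t.name, "")
            cell = cell.strip() if isinstance(cell, str) else ""
            where = f"{where_row}, column {t.name!r}"
            if cell == "":
                records[t.name].append(
                    math.nan if t.kind == "continuous" else None
                )
            elif t.kind == "continuous":
                if t.name == "Substrate breadth" and "|" in cell:
                    records[t.name].append(
                        derive_substrate_breadth(cell.split("|"))
                    )
                else:
                    records[t.name].append(
                        _parse_continuous(cell, where=where, log=log)
                    )
            elif t.kind == "binary":
                records[t.name].append(_parse_binary(cell, where=where))
            else:
                label = cell.strip().lower()
                if label not in t.attributes:
                    raise TraitMatrixError(
                        f"{where}: {label!r} not in {t.attributes}"
                    )
                records[t.name].append(label)

    data = pd.DataFrame(records, index=pd.Index(raw["species"], name="species"))
    data.insert(0, "iucn_category", raw["iucn_category"].str.strip().values)
    data.insert(
        1,
        "threat_status",
        pd.array([s if s != DD else pd.NA for s in statuses], dtype="Int64"),
    )
    log.append(f"parsed {len(data)} species from {path}")
    return TraitMatrix(data=data, definitions=list(registry), log=log)


def write_trait_matrix(matrix: TraitMatrix, path) -> None:
    """Write the matrix back to CSV ("" for missing); round-trips exactly."""
    out = matrix.data.drop(columns=["threat_status"]).copy()
    out.to_csv(path, na_rep="")


# ---------------------------------------------------------------------- #
# preprocessing


def impute_binary_absence(matrix: TraitMatrix) -> TraitMatrix:
    """Fill missing binary presence-type cells with "absent".

    Applies only to presence-type binary traits; continuous and categorical
    missing cells are untouched.  The number of imputations is logged.
    """
    out = matrix.copy()
    n_imputed = 0
    for name in PRESENCE_TYPE_TRAITS:
        if name not in out.data.columns:
            continue
        missing = out.data[name].isna()
        n_imputed += int(missing.sum())
        out.data.loc[missing, name] = "absent"
    out.log.append(f"imputed {n_imputed} missing binary cells as absent")
    return out


def zscale(matrix: TraitMatrix, trait: str, params="estimate") -> TraitMatrix:
    """Replace a continuous trait's values by z-scores.

    ``params`` is either a :class:`ScalingParams` or the string "estimate",
    in which case the mean and sample SD (n−1) are computed from non-missing
    values of non-DD records — DD species are the prediction set and never
    inform the scaling.
    """
    tdef = matrix.definition(trait)
    if tdef.kind != "continuous":
        raise TraitMatrixError(f"zscale applies to continuous traits, not {trait!r}")
    if params == "estimate":
        fit_values = matrix.non_dd()[trait].dropna().astype(float)
        sd = float(fit_values.std(ddof=1))
        if not sd > 0:
            raise TraitMatrixError(f"degenerate trait {trait!r}: sd = {sd}")
        params = ScalingParams(mean=float(fit_values.mean()), sd=sd)
    elif not isinstance(params, ScalingParams):
        raise TypeError("params must be ScalingParams or 'estimate'")

    out = matrix.copy()
    out.data[trait] = params.transform(out.data[trait].astype(float))
    out.scaling[trait] = params
    out.log.append(f"z-scaled {trait!r} with mean={params.mean}, sd={params.sd}")
    return out


def zscale_all(matrix: TraitMatrix) -> TraitMatrix:
    """z-scale every continuous trait (estimating parameters from the data)."""
    out = matrix
    for t in matrix.definitions:
        if t.kind == "continuous" and t.name in matrix.data.columns:
            out = zscale(out, t.name)
    return out
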