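"""Canonical registry of the fifteen moss functional traits.

Each trait is one of three kinds:

* ``binary`` — presence/absence of a structure (e.g. sporophyte presence).
  Empty cells in source data mean *absent*, because taxonomic descriptions
  only report structures that are there.
* ``categorical`` — a small closed set of attribute labels; the first label
  listed is the reference level used when the trait enters a model.
* ``continuous`` — a non-negative measurement (mm, µm) or count, z-scaled
  before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field


BINARY_LEVELS = ("absent", "present")


@dataclass(frozen=True)
class TraitDefinition:
    """Definition of a single functional trait.

    Parameters
    ----------
    name : str
        Canonical trait name, e.g. ``"Seta length"``.
    kind : {"binary", "categorical", "continuous"}
        Value domain of the trait.
    attributes : tuple of str
        Allowed category labels (categorical traits only); the first entry
        is the reference level.
    units : str
        Measurement units for continuous traits ("mm", "µm", "count"), or
        ``""`` for binary/categorical traits.
    """

    name: str
    kind: str
    attributes: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown trait kind: {self.kind!r}")
        if self.kind == "categorical" and len(self.attributes) < 2:
            raise ValueError(f"categorical trait {self.name!r} needs >= 2 attributes")


#: The fifteen traits of the analysis, in canonical order.  Categorical
#: attribute groupings beyond those named in the source analysis (plant sex,
#: capsule on seta, seta shape) are package choices.
CANONICAL_TRAITS: tuple[TraitDefinition, ...] = (
    TraitDefinition("Plant sex", "categorical", ("dioicous", "monoicous")),
    TraitDefinition("Sporophyte presence", "binary"),
    TraitDefinition("Vegetative reproduction", "binary"),
    TraitDefinition("Capsule length", "continuous", units="mm"),
    TraitDefinition("Capsule shape", "categorical", ("cylindric", "ovoid")),
    TraitDefinition("Capsule on seta", "categorical", ("erect", "pendent")),
    TraitDefinition("Seta length", "continuous", units="mm"),
    TraitDefinition("Seta shape", "categorical", ("straight", "curved")),
    TraitDefinition("Spore diameter", "continuous", units="µm"),
    TraitDefinition("Spore shape", "categorical", ("spherical", "ellipsoidal")),
    TraitDefinition("Spore ornamentation", "categorical", ("smooth", "papillose")),
    TraitDefinition("Persistent protonema", "binary"),
    TraitDefinition("Leaf length", "continuous", units="mm"),
    TraitDefinition("Stem length", "continuous", units="mm"),
    TraitDefinition("Substrate breadth", "continuous", units="count"),
)

TRAIT_NAMES: tuple[str, ...] = tuple(t.name for t in CANONICAL_TRAITS)

#: Sporophyte-morphology traits: recorded only when a sporophyte has been
#: observed; their joint absence defines the MAM2-ineligible block.
SPOROPHYTE_MORPHOLOGY_TRAITS: tuple[str, ...] = (
    "Capsule length",
    "Capsule shape",
    "Capsule on seta",
    "Seta length",
    "Seta shape",
    "Spore diameter",
    "Spore shape",
    "Spore ornamentation",
)

#: Binary presence-type traits subject to the empty-cell-means-absent rule.
PRESENCE_TYPE_TRAITS: tuple[str, ...] = (
    "Sporophyte presence",
    "Vegetative reproduction",
    "Persistent protonema",
)


def get_trait(name: str) -> TraitDefinition:
    for t in CANONICAL_TRAITS:
        if t.name == name:
            return t
    raise KeyError(f"unknown trait: {name!r}")
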