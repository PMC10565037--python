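"""Registry of the 22 crop-usage/taxon mapping properties.

The vocabulary lives at two levels mirroring the two-level taxonomy model:

* **annotation properties** (10) link a crop usage to a *taxon* (an OWL
  class). The candidate property ``hasTaxon`` is specialized into reference,
  generic, specific and invalid variants, each with an inverse running from
  the taxon to the usage.
* **object properties** (12) link a crop usage to a taxon *scientific name*
  (a SKOS concept). The five families mirror the annotation ones, plus two
  synonymous properties without inverses. Every usage→name property carries a
  **companion** annotation property: asserting a name-level mapping requires
  the corresponding taxon-level mapping on the same crop usage.

Four *invalid* properties are negative: they assert that a mapping should
NOT exist (the taxon/name cannot fulfil or identify the usage).
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from types import MappingProxyType

from .errors import UnknownPredicateError, WrongKindError

__all__ = ["PredicateSpec", "PredicateRegistry", "registry", "inverse_of",
           "companion_of", "is_negative"]

#: CURIE prefix under which the vocabulary defines its properties.
VOCAB_PREFIX = "ontofcu"
#: predicate_id spelling used in published SSSOM TSV rows.
SSSOM_PREDICATE_PREFIX = "fcu:def"


@dataclass(frozen=True)
class PredicateSpec:
    """Operational metadata for one mapping property."""

    name: str                     # bare property name, e.g. "hasReferenceTaxon"
    kind: str                     # "annotation" | "object"
    level: str                    # "taxon" | "name"
    direction: str                # "usage_to_entity" | "entity_to_usage"
    category: str                 # candidate/reference/generic/specific/invalid/
                                  # synonymous_scientific/synonymous_vernacular
    inverse_name: str | None = None
    companion_name: str | None = None

    @property
    def curie(self) -> str:
        return f"{VOCAB_PREFIX}:{self.name}"

    @property
    def sssom_predicate_id(self) -> str:
        """The spelling used in the SSSOM TSV predicate_id column."""
        return f"{SSSOM_PREDICATE_PREFIX}/{self.name}"

    @property
    def label(self) -> str:
        """Human-readable label, e.g. "Has reference taxon"."""
        words = re.sub(r"(?<!^)(?=[A-Z])", " ", self.name).lower()
        return words[0].upper() + words[1:]

    @property
    def negative(self) -> bool:
        return self.category == "invalid"


# (name, category, inverse) for the five annotation pairs; the first of each
# pair runs usage→taxon, the inverse taxon→usage
_ANNOTATION_PAIRS = [
    ("hasTaxon", "candidate", "hasUsage"),
    ("hasGenericTaxon", "generic", "hasSpecificUsage"),
    ("hasInvalidTaxon", "invalid", "hasInvalidUsage"),
    ("hasReferenceTaxon", "reference", "hasReferenceUsage"),
    ("hasSpecificTaxon", "specific", "hasGenericUsage"),
]

# (name, category, inverse, companion) for the five object pairs
_OBJECT_PAIRS = [
    ("hasScientificName", "candidate", "hasVernacularName", "hasTaxon"),
    ("hasGenericScientificName", "generic", "hasSpecificVernacularName", "hasGenericTaxon"),
    ("hasInvalidScientificName", "invalid", "hasInvalidVernacularName", "hasInvalidTaxon"),
    ("hasReferenceScientificName", "reference", "hasReferenceVernacularName",
     "hasReferenceTaxon"),
    ("hasSpecificScientificName", "specific", "hasGenericVernacularName", "hasSpecificTaxon"),
]


def _build_specs() -> dict[str, PredicateSpec]:
    specs: dict[str, PredicateSpec] = {}

    def add(spec: PredicateSpec) -> None:
        specs[spec.name] = spec

    for name, category, inverse in _ANNOTATION_PAIRS:
        add(PredicateSpec(name=name, kind="annotation", level="taxon",
                          direction="usage_to_entity", category=category,
                          inverse_name=inverse))
        add(PredicateSpec(name=inverse, kind="annotation", level="taxon",
                          direction="entity_to_usage", category=category,
                          inverse_name=name))
    for name, category, inverse, companion in _OBJECT_PAIRS:
        add(PredicateSpec(name=name, kind="object", level="name",
                          direction="usage_to_entity", category=category,
                          inverse_name=inverse, companion_name=companion))
        add(PredicateSpec(name=inverse, kind="object", level="name",
                          direction="entity_to_usage", category=category,
                          inverse_name=name))
    # the two synonymous properties have no declared inverse; both require the
    # reference taxon-level mapping as companion. hasSynonymousVernacularName
    # runs from a scientific name to a crop usage, opposite to its siblings.
    add(PredicateSpec(name="hasSynonymousScientificName", kind="object", level="name",
                      direction="usage_to_entity", category="synonymous_scientific",
                      companion_name="hasReferenceTaxon"))
    add(PredicateSpec(name="hasSynonymousVernacularName", kind="object", level="name",
                      direction="entity_to_usage", category="synonymous_vernacular",
                      companion_name="hasReferenceTaxon"))
    return specs


class PredicateRegistry:
    """Immutable lookup table over the 22 mapping properties.

    Lookup accepts the bare name (``hasReferenceTaxon``), the vocabulary CURIE
    (``ontofcu:hasReferenceTaxon``) or the published predicate_id spelling
    (``fcu:def/hasReferenceTaxon``).
    """

    def __init__(self):
        self._specs = MappingProxyType(_build_specs())

    @property
    def specs(self):
        return self._specs

    @staticmethod
    def _bare(identifier: str) -> str:
        name = identifier.rsplit("/", 1)[-1]
        name = name.rsplit(":", 1)[-1]
        name = name.rsplit("#", 1)[-1]
        return name

    def __contains__(self, identifier: str) -> bool:
        return self._bare(identifier) in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def get(self, identifier: str) -> PredicateSpec:
        name = self._bare(identifier)
        try:
            return self._specs[name]
        except KeyError:
            raise UnknownPredicateError(f"unknown mapping predicate {identifier!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, PredicateRegistry) and dict(self._specs) == dict(other._specs)

    def to_json(self, indent: int = 2) -> str:
        """Export the registry as a JSON document (for docs and error messages)."""
        doc = {
            spec.curie: {
                "kind": spec.kind,
                "level": spec.level,
                "direction": spec.direction,
                "category": spec.category,
                "inverse": spec.inverse_name,
                "companion": spec.companion_name,
                "negative": spec.negative,
            }
            for spec in sorted(self, key=lambda s: s.name)
        }
        return json.dumps(doc, indent=indent, ensure_ascii=False)


_REGISTRY = PredicateRegistry()


def registry() -> PredicateRegistry:
    """The (deterministic, immutable) mapping-property registry."""
    return _REGISTRY


def inverse_of(reg: PredicateRegistry, identifier: str) -> str | None:
    """CURIE of the inverse property, or None for the two synonymous ones."""
    spec = reg.get(identifier)
    if spec.inverse_name is None:
        return None
    return reg.get(spec.inverse_name).curie


def companion_of(reg: PredicateRegistry, identifier: str) -> str:
    """The annotation property that must accompany a name-level mapping."""
    spec = reg.get(identifier)
    if spec.kind != "object":
        raise WrongKindError(f"{spec.curie} is an annotation property; it has no companion")
    if spec.companion_name is None:
        raise WrongKindError(f"{spec.curie} ({spec.direction}) declares no companion")
    return reg.get(spec.companion_name).curie


def is_negative(reg: PredicateRegistry, identifier: str) -> bool:
    """True exactly for the four invalid-family (negative) properties."""
    return reg.get(identifier).negative
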