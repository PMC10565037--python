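"""SSSOM-aligned mapping records, mapping sets and cardinality.

A mapping links one subject (a crop usage, ``skos:Concept``) to one object
(a taxon, ``owl:Class``, or a scientific name, ``skos:Concept``) through a
registered predicate, with a confidence in [0, 1], a semapv justification
and provenance (author, reviewer, date, curation-rule text).

``mapping_cardinality`` is a convenience field derivable from the set: it is
recomputed here over positive (non-invalid) mappings, separately within each
predicate level, by counting distinct partners on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .curies import CurieMap
from .errors import ConfidenceError, MergeError
from .vocabulary import PredicateRegistry, registry

__all__ = ["MappingSetMeta", "Mapping", "MappingSet", "new_mapping",
           "compute_cardinality", "merge_sets", "MANUAL_CURATION"]

#: semapv term recorded for manually curated mappings.
MANUAL_CURATION = "semapv:ManualMappingCuration"

_CARDINALITIES = {"1:1", "1:n", "n:1", "1:0", "0:1", "n:n"}


@dataclass(frozen=True)
class MappingSetMeta:
    """Set-level metadata (the embedded-YAML block of an SSSOM TSV)."""

    mapping_set_id: str
    license: str
    curie_map: CurieMap = field(default_factory=CurieMap.default)
    creator_id: str | None = None
    creator_label: str | None = None
    subject_source: str | None = None
    subject_source_version: str | None = None
    object_source: str | None = None
    object_source_version: str | None = None

    def __post_init__(self):
        if not self.mapping_set_id:
            raise ValueError("mapping_set_id must be non-empty")
        if not self.license:
            raise ValueError("license must be non-empty")


@dataclass(frozen=True)
class Mapping:
    """One subject–predicate–object assertion with provenance."""

    subject_id: str
    predicate_id: str
    object_id: str
    confidence: float = 1.0
    mapping_justification: str = MANUAL_CURATION
    subject_label: str | None = None
    predicate_label: str | None = None
    object_label: str | None = None
    mapping_cardinality: str | None = None
    subject_type: str | None = None
    object_type: str | None = None
    author_id: str | None = None
    author_label: str | None = None
    reviewer_id: str | None = None
    reviewer_label: str | None = None
    mapping_date: str | None = None
    curation_rule_text: str | None = None
    comment: str | None = None
    extras: tuple[tuple[str, str], ...] = ()  # unknown TSV columns, preserved

    def __post_init__(self):
        for fieldname in ("subject_id", "predicate_id", "object_id"):
            if not getattr(self, fieldname):
                raise ValueError(f"{fieldname} must be non-empty")
        if not (0.0 <= self.confidence <= 1.0):
            raise ConfidenceError(f"confidence {self.confidence} outside [0, 1]")
        if self.mapping_cardinality is not None:
            card = self.mapping_cardinality.lower()
            if card not in _CARDINALITIES:
                raise ValueError(f"bad mapping_cardinality {self.mapping_cardinality!r}")
            object.__setattr__(self, "mapping_cardinality", card)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_id, self.predicate_id, self.object_id)


@dataclass
class MappingSet:
    """Set metadata plus an ordered list of mappings.

    Duplicate (subject, predicate, object) triples are tolerated in memory
    (the validator reports them; :func:`merge_sets` collapses them).
    """

    meta: MappingSetMeta
    mappings: list[Mapping] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mappings)

    def __iter__(self):
        return iter(self.mappings)


def new_mapping(subject_id: str, predicate: str, object_id: str,
                confidence: float = 1.0, *,
                reg: PredicateRegistry | None = None,
                subject_label: str | None = None,
                object_label: str | None = None,
                author_id: str | None = None,
                author_label: str | None = None,
                reviewer_id: str | None = None,
                reviewer_label: str | None = None,
                mapping_date: str | None = None,
                curation_rule_text: str | None = None,
                comment: str | None = None) -> Mapping:
    """Build a mapping, auto-filling types and labels from the predicate.

    The entity side (the taxon or name) is typed from the predicate level —
    ``owl:Class`` for taxon-level, ``skos:Concept`` for name-level — and the
    crop-usage side is always ``skos:Concept``. For the usual usage→entity
    direction the usage is the subject; for inverse properties the roles swap.
    The justification defaults to manual curation.
    """
    reg = reg or registry()
    spec = reg.get(predicate)
    entity_type = "owl:Class" if spec.level == "taxon" else "skos:Concept"
    if spec.direction == "usage_to_entity":
        subject_type, object_type = "skos:Concept", entity_type
    else:
        subject_type, object_type = entity_type, "skos:Concept"
    return Mapping(
        subject_id=subject_id,
        predicate_id=spec.sssom_predicate_id,
        predicate_label=spec.label,
        object_id=object_id,
        confidence=confidence,
        subject_label=subject_label,
        object_label=object_label,
        subject_type=subject_type,
        object_type=object_type,
        author_id=author_id,
        author_label=author_label,
        reviewer_id=reviewer_id,
        reviewer_label=reviewer_label,
        mapping_date=mapping_date,
        curation_rule_text=curation_rule_text,
        comment=comment,
    )


def compute_cardinality(mapping_set: MappingSet,
                        reg: PredicateRegistry | None = None) -> MappingSet:
    """Return a set with ``mapping_cardinality`` filled on every positive mapping.

    Counting runs over positive (non-invalid) mappings only, separately
    within each predicate level (taxon vs name): mixing levels would conflate
    a usage's taxa with its names, and invalid mappings assert
    non-correspondence. For a mapping let ``d_s`` be the number of distinct
    objects mapped from its subject and ``d_o`` the number of distinct
    subjects mapped to its object (within the same level):

    * ``1:1`` when d_s = 1 and d_o = 1,
    * ``1:n`` when d_s > 1 and d_o = 1 (the subject maps to several objects),
    * ``n:1`` when d_s = 1 and d_o > 1,
    * ``n:n`` otherwise.

    Invalid-predicate mappings keep no cardinality. Unregistered predicates
    are left untouched (the validator reports them). Idempotent and
    order-insensitive.
    """
    reg = reg or registry()
    by_level_subject: dict[tuple[str, str], set[str]] = {}
    by_level_object: dict[tuple[str, str], set[str]] = {}
    for m in mapping_set.mappings:
        if m.predicate_id not in reg:
            continue
        spec = reg.get(m.predicate_id)
        if spec.negative:
            continue
        by_level_subject.setdefault((spec.level, m.subject_id), set()).add(m.object_id)
        by_level_object.setdefault((spec.level, m.object_id), set()).add(m.subject_id)

    out: list[Mapping] = []
    for m in mapping_set.mappings:
        if m.predicate_id not in reg:
            out.append(m)
            continue
        spec = reg.get(m.predicate_id)
        if spec.negative:
            out.append(replace(m, mapping_cardinality=None))
            continue
        d_s = len(by_level_subject[(spec.level, m.subject_id)])
        d_o = len(by_level_object[(spec.level, m.object_id)])
        if d_s == 1 and d_o == 1:
            card = "1:1"
        elif d_s > 1 and d_o == 1:
            card = "1:n"
        elif d_s == 1 and d_o > 1:
            card = "n:1"
        else:
            card = "n:n"
        out.append(replace(m, mapping_cardinality=card))
    return MappingSet(meta=mapping_set.meta, mappings=out)


def merge_sets(a: MappingSet, b: MappingSet) -> MappingSet:
    """Union of two sets; exact-duplicate triples collapse to the earliest date.

    Metadata comes from *a* with the CURIE maps unioned; a prefix bound to
    different IRIs in the two maps is a :class:`MergeError`.
    """
    curie_map = a.meta.curie_map.merged_with(b.meta.curie_map)
    meta = replace(a.meta, curie_map=curie_map)
    chosen: dict[tuple[str, str, str], Mapping] = {}
    order: list[tuple[str, str, str]] = []
    for m in list(a.mappings) + list(b.mappings):
        key = m.triple
        if key not in chosen:
            chosen[key] = m
            order.append(key)
        else:
            kept = chosen[key]
            if (m.mapping_date or "~") < (kept.mapping_date or "~"):
                chosen[key] = m
    return MappingSet(meta=meta, mappings=[chosen[k] for k in order])
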