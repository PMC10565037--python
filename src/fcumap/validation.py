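"""Consistency checking of mapping sets and obsolescence diffing.

The validator enforces the vocabulary semantics (predicate levels and the
companion requirement), the reference/synonym status of name targets, the
publication policy (confidence 1) and set hygiene (duplicates, CURIE
prefixes, cardinality freshness). Issue codes are frozen API:

======  ========  =======================================================
code    severity  meaning
======  ========  =======================================================
E1      error     unregistered mapping predicate
E2      error     subject/object type inconsistent with predicate level
E3      error     name-level mapping without its companion taxon-level
                  mapping on the same subject and corresponding taxon
E4      error     reference-scientific-name target is not the reference
                  name of the companion taxon
E5      error     synonymous-scientific-name target is not a synonym
E6      error     positive and invalid mapping on the same subject/object
E7      error     confidence outside [0, 1]
E8      error     duplicate (subject, predicate, object) triple
E9      error     CURIE prefix missing from the set's curie map
W1      warning   subject not a strict descendant of the usages branch
W2      warning   subject has reference taxa but none at rank species
W3      warning   stored cardinality differs from recomputed
W4      warning   confidence below 1 (publication policy)
======  ========  =======================================================

Graph evolution (taxa merge, split, change rank; names change status)
invalidates mappings; :func:`find_obsolete` flags those against new graph
versions and suggests predicate swaps where a name's status flipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .graph_model import Rank, TaxonomyGraph, UsageThesaurus, is_crop_usage
from .mapping_core import Mapping, MappingSet, compute_cardinality
from .vocabulary import PredicateRegistry, registry

__all__ = ["Issue", "ValidationReport", "DiffReport", "validate",
           "check_publishable", "find_obsolete"]


@dataclass(frozen=True)
class Issue:
    code: str
    severity: str  # "error" | "warning"
    message: str
    mapping_index: int | None = None


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(issue.severity for issue in self.issues))

    @property
    def passed(self) -> bool:
        return not any(issue.severity == "error" for issue in self.issues)

    def codes(self) -> list[str]:
        return sorted(issue.code for issue in self.issues)

    def to_text(self) -> str:
        if not self.issues:
            return "OK: no issues\n"
        lines = []
        for issue in self.issues:
            where = f" [mapping {issue.mapping_index}]" if issue.mapping_index is not None else ""
            lines.append(f"{issue.severity.upper()} {issue.code}{where}: {issue.message}")
        return "\n".join(lines) + "\n"

    def to_json_obj(self) -> dict:
        return {
            "passed": self.passed,
            "counts": self.counts,
            "issues": [
                {"code": i.code, "severity": i.severity, "message": i.message,
                 "mapping_index": i.mapping_index}
                for i in self.issues
            ],
        }


@dataclass
class DiffReport:
    """Mappings invalidated by graph evolution, with replacement hints."""

    obsolete: list[tuple[Mapping, str]] = field(default_factory=list)
    suggestions: list[tuple[Mapping, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.obsolete


def _expected_types(spec) -> tuple[str, str]:
    entity = "owl:Class" if spec.level == "taxon" else "skos:Concept"
    if spec.direction == "usage_to_entity":
        return "skos:Concept", entity
    return entity, "skos:Concept"


def validate(mapping_set: MappingSet, taxonomy: TaxonomyGraph,
             thesaurus: UsageThesaurus,
             reg: PredicateRegistry | None = None) -> ValidationReport:
    """Check a mapping set against the vocabulary semantics and guidelines.

    All findings are report entries; nothing raises. The report is
    order-insensitive: permuting the mappings changes indices but not the
    multiset of issue codes.
    """
    reg = reg or registry()
    report = ValidationReport()
    add = report.issues.append

    known = [(i, m, reg.get(m.predicate_id) if m.predicate_id in reg else None)
             for i, m in enumerate(mapping_set.mappings)]

    # set-level indices used by per-mapping checks
    taxon_level_pairs: set[tuple[str, str, str]] = set()   # (subject, bare pred, taxon)
    positive_pairs: dict[tuple[str, str], list[str]] = {}  # (subject, object) -> polarity
    for _, m, spec in known:
        if spec is None:
            continue
        if spec.level == "taxon":
            taxon_level_pairs.add((m.subject_id, spec.name, m.object_id))
        positive_pairs.setdefault((m.subject_id, m.object_id), []).append(
            "invalid" if spec.negative else "positive")

    recomputed = compute_cardinality(mapping_set, reg=reg).mappings

    for i, m, spec in known:
        if spec is None:
            add(Issue("E1", "error", f"unknown predicate {m.predicate_id!r}", i))
            continue
        exp_subject, exp_object = _expected_types(spec)
        if m.subject_type is not None and m.subject_type != exp_subject:
            add(Issue("E2", "error",
                      f"subject_type {m.subject_type!r} but {spec.curie} expects "
                      f"{exp_subject!r}", i))
        if m.object_type is not None and m.object_type != exp_object:
            add(Issue("E2", "error",
                      f"object_type {m.object_type!r} but {spec.curie} expects "
                      f"{exp_object!r}", i))
        if not (0.0 <= m.confidence <= 1.0):
            add(Issue("E7", "error", f"confidence {m.confidence} outside [0, 1]", i))
        elif m.confidence < 1.0:
            add(Issue("W4", "warning",
                      f"confidence {m.confidence} < 1; publication policy requires 1", i))

        if spec.level == "name" and spec.direction == "usage_to_entity":
            companion = reg.get(spec.companion_name)
            target = taxonomy.names.get(m.object_id)
            owner = target.taxon_id if target is not None else None
            if owner is None or (m.subject_id, companion.name, owner) not in taxon_level_pairs:
                add(Issue("E3", "error",
                          f"{spec.curie} mapping lacks companion {companion.curie} "
                          f"on subject {m.subject_id} and the taxon owning {m.object_id}", i))
            if target is not None:
                if spec.category == "reference" and target.status != "reference":
                    add(Issue("E4", "error",
                              f"{m.object_id} is not the reference name of its taxon", i))
                if spec.category == "synonymous_scientific" and target.status != "synonym":
                    add(Issue("E5", "error",
                              f"{m.object_id} is not a synonym name", i))

        if m.mapping_cardinality is not None:
            fresh = recomputed[i].mapping_cardinality
            if m.mapping_cardinality != fresh:
                add(Issue("W3", "warning",
                          f"stored cardinality {m.mapping_cardinality!r} != "
                          f"recomputed {fresh!r}", i))

        if spec.direction == "usage_to_entity":
            subject = m.subject_id
            if subject in thesaurus.concepts and not is_crop_usage(thesaurus, subject):
                add(Issue("W1", "warning",
                          f"subject {subject} is not a strict descendant of the "
                          f"usages branch", i))

        for identifier in (m.subject_id, m.predicate_id, m.object_id):
            if mapping_set.meta.curie_map.is_curie(identifier):
                prefix = identifier.partition(":")[0]
                if prefix not in mapping_set.meta.curie_map.bindings:
                    add(Issue("E9", "error",
                              f"prefix {prefix!r} of {identifier!r} missing from "
                              f"curie_map", i))

    # E6: positive/invalid conflict on the same (subject, object)
    for (subject, obj), polarities in sorted(positive_pairs.items()):
        if "positive" in polarities and "invalid" in polarities:
            add(Issue("E6", "error",
                      f"both positive and invalid mappings between {subject} and {obj}"))

    # E8: duplicate triples
    triples = Counter(m.triple for m in mapping_set.mappings)
    for triple, count in sorted(triples.items()):
        if count > 1:
            add(Issue("E8", "error", f"duplicate triple {triple} ({count} occurrences)"))

    # W2: a subject with reference taxa should have at least one at rank species
    ref_taxa_by_subject: dict[str, list[str]] = {}
    for _, m, spec in known:
        if spec is not None and spec.name == "hasReferenceTaxon":
            ref_taxa_by_subject.setdefault(m.subject_id, []).append(m.object_id)
    for subject, taxa in sorted(ref_taxa_by_subject.items()):
        ranks = [taxonomy.taxa[t].rank for t in taxa if t in taxonomy.taxa]
        if ranks and Rank.SPECIES not in ranks:
            add(Issue("W2", "warning",
                      f"subject {subject} has reference taxa but none at rank species"))
    return report


def check_publishable(mapping_set: MappingSet, taxonomy: TaxonomyGraph,
                      thesaurus: UsageThesaurus,
                      reg: PredicateRegistry | None = None) -> tuple[bool, ValidationReport]:
    """Publication gate: zero errors, every confidence exactly 1, mandatory
    SSSOM fields present."""
    report = validate(mapping_set, taxonomy, thesaurus, reg=reg)
    ok = report.passed
    for i, m in enumerate(mapping_set.mappings):
        if m.confidence != 1.0:
            ok = False
        for fieldname in ("subject_id", "predicate_id", "object_id",
                          "mapping_justification"):
            if not getattr(m, fieldname):
                report.issues.append(Issue("E7", "error",
                                           f"missing mandatory field {fieldname}", i))
                ok = False
    return ok, report


def find_obsolete(mapping_set: MappingSet, new_taxonomy: TaxonomyGraph,
                  new_thesaurus: UsageThesaurus,
                  old_taxonomy: TaxonomyGraph | None = None,
                  reg: PredicateRegistry | None = None) -> DiffReport:
    """Flag mappings invalidated by new versions of the two graphs.

    Reasons: ``subject_missing`` (usage gone from the thesaurus),
    ``object_missing`` (taxon or name gone from the taxonomy),
    ``name_status_changed`` (a reference-name target demoted to synonym or a
    synonym promoted, with a predicate-swap suggestion), and — when the
    previous taxonomy version is supplied — ``rank_changed`` for taxon-level
    mappings whose taxon moved rank.
    """
    reg = reg or registry()
    report = DiffReport()
    for m in mapping_set.mappings:
        if m.predicate_id not in reg:
            continue
        spec = reg.get(m.predicate_id)
        usage_id, entity_id = ((m.subject_id, m.object_id)
                               if spec.direction == "usage_to_entity"
                               else (m.object_id, m.subject_id))
        if usage_id not in new_thesaurus.concepts:
            report.obsolete.append((m, "subject_missing"))
            continue
        if spec.level == "taxon":
            taxon = new_taxonomy.taxa.get(entity_id)
            if taxon is None:
                report.obsolete.append((m, "object_missing"))
                continue
            if old_taxonomy is not None:
                old = old_taxonomy.taxa.get(entity_id)
                if old is not None and old.rank != taxon.rank:
                    report.obsolete.append((m, "rank_changed"))
        else:
            name = new_taxonomy.names.get(entity_id)
            if name is None:
                report.obsolete.append((m, "object_missing"))
                continue
            if spec.category == "reference" and name.status == "synonym":
                report.obsolete.append((m, "name_status_changed"))
                report.suggestions.append((m, "hasSynonymousScientificName"))
            elif spec.category == "synonymous_scientific" and name.status == "reference":
                report.obsolete.append((m, "name_status_changed"))
                report.suggestions.append((m, "hasReferenceScientificName"))
    return report
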