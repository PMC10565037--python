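"""Executable curation rules producing high-confidence mappings.

Three documented rules justify how mappings between crop usages and taxa are
asserted, each tied to a reference source of information:

* **CR_Geves** — a record from the official French catalogue of cultivated
  species and varieties gives a vernacular name (*Common species*), a crop
  usage (*Category*) and a scientific name (*Botanical species*). The most
  specific matching crop usage in the usages branch and the taxon carrying
  the scientific name are resolved; any ambiguity means no mapping.
* **CR_C3PO_KB** — a crop-production knowledge-base record directly pairs a
  crop-usage IRI with a scientific-name IRI; the taxon is reached by
  following the reference-name link backwards.
* **CR_Experts** — an expert asserts that a scientific name is linked to a
  crop usage. Depending on whether the name resolves as a reference name, a
  synonym, or not at all (with a resolvable parent name), two or three
  mappings are created, escalating to the generic properties in the last
  case.

Every emitted mapping has confidence exactly 1 — only totally confident
mappings are published — and failures are *skipped outcomes*, never
exceptions. Name-level mappings always come with their companion taxon-level
mapping.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field

from .errors import WrongLevelError
from .graph_model import (TaxonomyGraph, UsageThesaurus, find_taxon_by_name,
                          is_crop_usage, reference_name)
from .mapping_core import (Mapping, MappingSet, MappingSetMeta, compute_cardinality,
                           new_mapping)
from .vocabulary import PredicateRegistry, registry

__all__ = ["GevesRecord", "C3poRecord", "ExpertAssertion", "CurationOutcome",
           "apply_cr_geves", "apply_cr_c3po", "apply_cr_experts",
           "derive_name_mappings", "curate_batch",
           "read_records_csv", "skipped_report_json"]

RULE_TEXTS = {
    "CR_Geves": ("CR_Geves: the experts found the mapping in the Official Catalog of "
                 "Species and Varieties of Cultivated Crops in France "
                 "[https://www.geves.fr/catalogue-france/]"),
    "CR_C3PO_KB": ("CR_C3PO_KB: the experts found the mapping in the C3PO knowledge "
                   "base plant module"),
    "CR_Experts": "CR_Experts: the experts proposed the mapping from their own knowledge",
}


@dataclass(frozen=True)
class GevesRecord:
    """One cultivar row of the GEVES-style catalogue."""

    common_species: str
    category: str
    botanical_species: str
    cultivar_label: str | None = None

    def __post_init__(self):
        if not self.common_species.strip() or not self.botanical_species.strip():
            raise ValueError("common_species and botanical_species must be non-empty")


@dataclass(frozen=True)
class C3poRecord:
    """A crop-usage IRI paired with a scientific-name IRI."""

    usage_id: str
    scientific_name_id: str


@dataclass(frozen=True)
class ExpertAssertion:
    """An expert's claim that a scientific name is linked to a crop usage."""

    usage_id: str
    scientific_name_text: str
    parent_name_text: str | None = None
    reviewer_id: str | None = None
    reviewer_label: str | None = None
    author_id: str | None = None
    author_label: str | None = None
    comment: str | None = None

    def __post_init__(self):
        if not self.scientific_name_text.strip():
            raise ValueError("scientific_name_text must be non-empty")


@dataclass(frozen=True)
class CurationOutcome:
    """Result of applying one rule to one record: mappings, or a reason."""

    rule_id: str
    mappings: tuple[Mapping, ...] = ()
    skipped: bool = False
    skip_reason: str | None = None

    def __post_init__(self):
        if self.skipped != (len(self.mappings) == 0):
            raise ValueError("skipped outcomes carry no mappings and vice versa")


def _skip(rule_id: str, reason: str) -> CurationOutcome:
    return CurationOutcome(rule_id=rule_id, skipped=True, skip_reason=reason)


def _fold(text: str) -> str:
    return unicodedata.normalize("NFC", text).casefold()


def _usage_pair(usage_id: str, taxon_pred: str, name_pred: str, taxon_id: str,
                taxonomy: TaxonomyGraph, thesaurus: UsageThesaurus, rule_id: str,
                **prov) -> list[Mapping]:
    """The (taxon-level, name-level) mapping pair targeting a taxon and its
    reference name, confidence 1, companion pairing guaranteed."""
    ref = reference_name(taxonomy, taxon_id)
    usage_label = thesaurus.concepts[usage_id].pref_label if usage_id in thesaurus.concepts else None
    rule_text = RULE_TEXTS[rule_id]
    return [
        new_mapping(usage_id, taxon_pred, taxon_id, 1.0,
                    subject_label=usage_label, object_label=ref.binomial,
                    curation_rule_text=rule_text, **prov),
        new_mapping(usage_id, name_pred, ref.id, 1.0,
                    subject_label=usage_label, object_label=ref.full_label,
                    curation_rule_text=rule_text, **prov),
    ]


# ---------------------------------------------------------------------------
# CR_Geves


def _resolve_geves_usage(record: GevesRecord, thesaurus: UsageThesaurus):
    """Most specific unique usage matching the record's common species and
    category, within the usages branch. Returns (usage_id, None) or
    (None, reason)."""
    needle = _fold(record.common_species)
    candidates = []
    for concept in thesaurus.concepts.values():
        if not is_crop_usage(thesaurus, concept.id):
            continue
        labels = {concept.pref_label, *concept.alt_labels}
        if any(needle in _fold(label) for label in labels):
            candidates.append(concept)
    if not candidates:
        return None, "usage not found"
    # narrow by category tokens when that keeps at least one candidate
    tokens = [t for t in _fold(record.category).split() if len(t) > 2]
    if tokens:
        narrowed = [
            c for c in candidates
            if any(tok in _fold(label) for tok in tokens
                   for label in {c.pref_label, *c.alt_labels})
        ]
        if narrowed:
            candidates = narrowed
    best_depth = max(thesaurus.depth(c.id) for c in candidates)
    deepest = sorted((c for c in candidates if thesaurus.depth(c.id) == best_depth),
                     key=lambda c: c.id)
    if len(deepest) > 1:
        return None, "ambiguous usage: " + ", ".join(c.id for c in deepest)
    return deepest[0].id, None


def apply_cr_geves(record: GevesRecord, thesaurus: UsageThesaurus,
                   taxonomy: TaxonomyGraph, **prov) -> CurationOutcome:
    """Apply the catalogue rule: resolve usage and taxon, emit two mappings.

    On unique resolution the outcome holds the reference-taxon mapping and
    the reference-scientific-name mapping, both at confidence 1. Any
    ambiguity or failed resolution yields a skipped outcome with a reason.
    """
    usage_id, reason = _resolve_geves_usage(record, thesaurus)
    if usage_id is None:
        return _skip("CR_Geves", reason)
    match = find_taxon_by_name(taxonomy, record.botanical_species)
    if match.status == "no_match":
        return _skip("CR_Geves", "taxon not found")
    if match.status == "ambiguous":
        return _skip("CR_Geves", "ambiguous taxon: "
                     + ", ".join(t for t, _ in match.candidates))
    mappings = _usage_pair(usage_id, "hasReferenceTaxon", "hasReferenceScientificName",
                           match.taxon_id, taxonomy, thesaurus, "CR_Geves", **prov)
    return CurationOutcome(rule_id="CR_Geves", mappings=tuple(mappings))


# ---------------------------------------------------------------------------
# CR_C3PO_KB


def apply_cr_c3po(record: C3poRecord, thesaurus: UsageThesaurus,
                  taxonomy: TaxonomyGraph, **prov) -> CurationOutcome:
    """Apply the knowledge-base rule: follow the name back to its taxon.

    The record's scientific-name IRI must resolve to a *reference* name; its
    taxon is reached by the is-reference-name-of link. A synonym contradicts
    the rule's premise and yields a skipped outcome, as do unresolvable IRIs.
    """
    if record.usage_id not in thesaurus.concepts:
        return _skip("CR_C3PO_KB", f"unknown usage {record.usage_id}")
    name = taxonomy.names.get(record.scientific_name_id)
    if name is None:
        return _skip("CR_C3PO_KB", f"unknown scientific name {record.scientific_name_id}")
    if name.status != "reference":
        return _skip("CR_C3PO_KB",
                     f"name {name.id} is a synonym, not a reference name")
    mappings = _usage_pair(record.usage_id, "hasReferenceTaxon",
                           "hasReferenceScientificName", name.taxon_id,
                           taxonomy, thesaurus, "CR_C3PO_KB", **prov)
    return CurationOutcome(rule_id="CR_C3PO_KB", mappings=tuple(mappings))


# ---------------------------------------------------------------------------
# CR_Experts


def apply_cr_experts(assertion: ExpertAssertion, thesaurus: UsageThesaurus,
                     taxonomy: TaxonomyGraph) -> CurationOutcome:
    """Apply the expert rule, branching on how the asserted name resolves.

    * reference name → 2 mappings (reference taxon + reference name);
    * synonym → 3 mappings (reference taxon + reference name + the matched
      synonym under the synonymous-scientific-name property);
    * no match but a resolvable parent name → 2 mappings escalated to the
      generic properties against the parent taxon;
    * otherwise → skipped.
    """
    prov = dict(author_id=assertion.author_id, author_label=assertion.author_label,
                reviewer_id=assertion.reviewer_id, reviewer_label=assertion.reviewer_label,
                comment=assertion.comment)
    if assertion.usage_id not in thesaurus.concepts:
        return _skip("CR_Experts", f"unknown usage {assertion.usage_id}")
    match = find_taxon_by_name(taxonomy, assertion.scientific_name_text)
    if match.status == "ambiguous":
        return _skip("CR_Experts", "ambiguous scientific name: "
                     + ", ".join(t for t, _ in match.candidates))
    if match.status == "match":
        mappings = _usage_pair(assertion.usage_id, "hasReferenceTaxon",
                               "hasReferenceScientificName", match.taxon_id,
                               taxonomy, thesaurus, "CR_Experts", **prov)
        if match.matched_status == "synonym":
            synonym = taxonomy.names[match.name_id]
            usage_label = thesaurus.concepts[assertion.usage_id].pref_label
            mappings.append(new_mapping(
                assertion.usage_id, "hasSynonymousScientificName", synonym.id, 1.0,
                subject_label=usage_label, object_label=synonym.full_label,
                curation_rule_text=RULE_TEXTS["CR_Experts"], **prov))
        return CurationOutcome(rule_id="CR_Experts", mappings=tuple(mappings))
    # no match: escalate to the parent name when the assertion provides one
    if assertion.parent_name_text:
        parent = find_taxon_by_name(taxonomy, assertion.parent_name_text)
        if parent.status == "match":
            mappings = _usage_pair(assertion.usage_id, "hasGenericTaxon",
                                   "hasGenericScientificName", parent.taxon_id,
                                   taxonomy, thesaurus, "CR_Experts", **prov)
            return CurationOutcome(rule_id="CR_Experts", mappings=tuple(mappings))
        return _skip("CR_Experts", "neither name nor parent name resolved")
    return _skip("CR_Experts", "scientific name not found")


# ---------------------------------------------------------------------------
# Derivation and batching

_CATEGORY_TO_NAME_PREDICATE = {
    "candidate": "hasScientificName",
    "reference": "hasReferenceScientificName",
    "generic": "hasGenericScientificName",
    "specific": "hasSpecificScientificName",
    "invalid": "hasInvalidScientificName",
}


def derive_name_mappings(taxon_mappings: list[Mapping], taxonomy: TaxonomyGraph,
                         reg: PredicateRegistry | None = None,
                         existing: list[Mapping] | None = None) -> list[Mapping]:
    """Derive name-level mappings from taxon-level ones.

    Each taxon-level mapping yields the name-level mapping of the same
    category (reference → reference scientific name, generic → generic, …)
    targeting the taxon's reference name, with provenance and confidence
    copied. Triples already present in *existing* (e.g. the output of a
    previous derivation) are not re-emitted, making derivation idempotent.
    """
    reg = reg or registry()
    seen: set[tuple[str, str, str]] = set()
    out: list[Mapping] = []
    for m in taxon_mappings:
        spec = reg.get(m.predicate_id)
        if spec.level != "taxon":
            raise WrongLevelError(f"{spec.curie} is name-level; expected taxon-level input")
        if spec.direction != "usage_to_entity":
            continue  # inverse annotations carry no derivable name mapping
        name_pred = reg.get(_CATEGORY_TO_NAME_PREDICATE[spec.category])
        ref = reference_name(taxonomy, m.object_id)
        derived = new_mapping(
            m.subject_id, name_pred.name, ref.id, m.confidence,
            subject_label=m.subject_label, object_label=ref.full_label,
            author_id=m.author_id, author_label=m.author_label,
            reviewer_id=m.reviewer_id, reviewer_label=m.reviewer_label,
            mapping_date=m.mapping_date, curation_rule_text=m.curation_rule_text,
            comment=m.comment)
        if derived.triple not in seen:
            seen.add(derived.triple)
            out.append(derived)
    present = {m.triple for m in taxon_mappings}
    present.update(m.triple for m in (existing or []))
    return [m for m in out if m.triple not in present]


def curate_batch(records, thesaurus: UsageThesaurus, taxonomy: TaxonomyGraph,
                 set_meta: MappingSetMeta) -> tuple[MappingSet, list[CurationOutcome]]:
    """Run every record through its rule; collect mappings and skips.

    Records are dispatched on type (:class:`GevesRecord`, :class:`C3poRecord`,
    :class:`ExpertAssertion`). The mapping union is deduplicated by triple
    (first occurrence wins) and cardinality is computed on the result.
    """
    outcomes: list[CurationOutcome] = []
    for record in records:
        if isinstance(record, GevesRecord):
            outcomes.append(apply_cr_geves(record, thesaurus, taxonomy))
        elif isinstance(record, C3poRecord):
            outcomes.append(apply_cr_c3po(record, thesaurus, taxonomy))
        elif isinstance(record, ExpertAssertion):
            outcomes.append(apply_cr_experts(record, thesaurus, taxonomy))
        else:
            raise TypeError(f"unknown record type {type(record).__name__}")
    mappings: list[Mapping] = []
    seen: set[tuple[str, str, str]] = set()
    for outcome in outcomes:
        for m in outcome.mappings:
            if m.triple not in seen:
                seen.add(m.triple)
                mappings.append(m)
    skipped = [o for o in outcomes if o.skipped]
    mapping_set = compute_cardinality(MappingSet(meta=set_meta, mappings=mappings))
    return mapping_set, skipped


# ---------------------------------------------------------------------------
# Record I/O

_DIALECTS = {
    "geves": (GevesRecord, ["common_species", "category", "botanical_species",
                            "cultivar_label"]),
    "c3po": (C3poRecord, ["usage_id", "scientific_name_id"]),
    "experts": (ExpertAssertion, ["usage_id", "scientific_name_text", "parent_name_text",
                                  "reviewer_id", "reviewer_label", "author_id",
                                  "author_label", "comment"]),
}


def read_records_csv(path, dialect: str):
    """Read curation records from CSV; *dialect* names the rule family
    ("geves", "c3po" or "experts") and fixes the expected header."""
    try:
        cls, columns = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown record dialect {dialect!r}") from None
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            kwargs = {col: (row.get(col) or None) for col in columns}
            for required in columns[:2]:
                if kwargs[required] is None:
                    raise ValueError(f"{path}: missing column {required!r}")
            records.append(cls(**kwargs))
    return records


def skipped_report_json(skipped: list[CurationOutcome], indent: int = 2) -> str:
    """Serialize skipped outcomes as a JSON report."""
    return json.dumps(
        [{"rule_id": o.rule_id, "reason": o.skip_reason} for o in skipped],
        indent=indent, ensure_ascii=False)
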