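"""In-memory models of the two aligned knowledge graphs.

Two-level taxonomy model
------------------------
The taxonomic side separates *taxonomy* from *nomenclature*: a taxon is an
OWL class placed at a rank, whose parent is the next higher-ranked taxon; its
scientific names are SKOS concepts attached to it, exactly one of them being
the reference name (the accepted name in zoology, the valid name in botany)
and the others synonyms. A name's label splits into the binomial (epithets
plus any rank infix such as ``subsp.`` or ``var.``) and the authority (author
citation with an optional year).

Crop-usage thesaurus
--------------------
The usage side is a SKOS concept scheme with French labels and two top
branches: one groups multi-usage cultivated plants, the other organizes
cultivated plants by agricultural usage (the branch curation works in).

Both models are loaded from a Turtle subset via :func:`load_graphs` and keep
ids as CURIE strings (``taxref:taxon/94503``); ids are compared as exact
strings after NFC normalization and never synthesized from labels.
"""

from __future__ import annotations

import enum
import logging
import re
import unicodedata
from dataclasses import dataclass, field, replace

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, SKOS

from .curies import CurieMap
from .errors import InvalidNameError, LoadError, MissingEntityError

logger = logging.getLogger(__name__)

__all__ = [
    "Rank",
    "ScientificName",
    "Taxon",
    "TaxonomyGraph",
    "CropUsage",
    "UsageThesaurus",
    "NameMatch",
    "parse_scientific_name",
    "find_taxon_by_name",
    "reference_name",
    "ancestors",
    "is_crop_usage",
    "search_usages_by_label",
    "load_graphs",
    "load_taxonomy",
    "load_thesaurus",
    "save_taxonomy",
    "save_thesaurus",
]


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def _squash(text: str) -> str:
    """NFC-normalize and collapse internal whitespace."""
    return " ".join(_nfc(text).split())


# ---------------------------------------------------------------------------
# Ranks


@enum.unique
class Rank(enum.IntEnum):
    """Taxonomic rank in a fixed total order of increasing specificity.

    Integer comparison follows specificity: ``Rank.SPECIES < Rank.SUBSPECIES``
    means *species* is less specific. The order below subspecies
    (variety < form < cultivar) follows botanical convention.
    """

    KINGDOM = 0
    PHYLUM = 1
    CLASS_ = 2
    ORDER_ = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6
    SUBSPECIES = 7
    VARIETY = 8
    FORM = 9
    CULTIVAR = 10

    @property
    def label(self) -> str:
        return self.name.lower().rstrip("_")

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        key = label.strip().lower().rstrip("_")
        for rank in cls:
            if rank.label == key:
                return rank
        raise ValueError(f"unknown rank {label!r}")


# ---------------------------------------------------------------------------
# Scientific-name parsing

#: Rank infixes that belong to the binomial part of an infraspecific name.
_RANK_INFIXES = frozenset({"subsp.", "ssp.", "var.", "subvar.", "f.", "cv.", "x", "×"})

_YEAR_SUFFIX = re.compile(r",?\s*\(?\d{4}\)?\.?\s*$")

_LOWER_WORD = re.compile(r"^[a-zà-öø-ÿ][a-zà-öø-ÿ-]*$")


def parse_scientific_name(label: str) -> tuple[str, str | None]:
    """Split a scientific-name label into (binomial, authority).

    The binomial keeps the epithets and any rank infix (``subsp.``/``var.``/
    ``f.``); the authority is the trailing author citation with its optional
    year, ``None`` when absent. Re-joining binomial and authority reproduces
    the input up to whitespace normalization.

    >>> parse_scientific_name("Daucus carota L., 1753")
    ('Daucus carota', 'L., 1753')
    """
    if not label or not label.strip():
        raise InvalidNameError("empty scientific-name label")
    tokens = _squash(label).split(" ")
    # genus, then epithets; an epithet is a lowercase word directly after the
    # genus or after a rank infix. Infraspecific names may interleave an
    # authority before a deeper rank infix ("… var. foliosum Hegi f.
    # cylindricum"), so the binomial extends through the LAST infix+epithet
    # pair; only what trails the final epithet is the authority.
    i = 1
    if i < len(tokens) and _LOWER_WORD.match(tokens[i]):
        i += 1
        j = i
        while j + 1 < len(tokens):
            if tokens[j].lower() in _RANK_INFIXES and _LOWER_WORD.match(tokens[j + 1]):
                j += 2
                i = j  # binomial reaches this epithet, across any mid-name authority
            else:
                j += 1
    binomial = " ".join(tokens[:i])
    authority = " ".join(tokens[i:]) or None
    return binomial, authority


def strip_year(authority: str | None) -> str | None:
    """Drop a trailing ``, <4-digit year>`` from an author citation.

    Sources that do not follow the nomenclature code strictly cite the
    authority without the date ("L." instead of "L., 1753"); matching
    tolerates that by comparing year-stripped citations.
    """
    if authority is None:
        return None
    stripped = _YEAR_SUFFIX.sub("", authority).strip()
    return stripped or None


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class ScientificName:
    """A regulated name attached to exactly one taxon."""

    id: str
    full_label: str
    binomial: str
    authority: str | None
    status: str  # "reference" | "synonym"
    taxon_id: str

    def __post_init__(self):
        if self.status not in ("reference", "synonym"):
            raise ValueError(f"bad name status {self.status!r}")
        expected = self.binomial if self.authority is None else f"{self.binomial} {self.authority}"
        if _squash(self.full_label) != _squash(expected):
            raise ValueError(
                f"full_label {self.full_label!r} != binomial + authority {expected!r}"
            )

    @classmethod
    def from_label(cls, id: str, full_label: str, status: str, taxon_id: str) -> "ScientificName":
        binomial, authority = parse_scientific_name(full_label)
        return cls(id=id, full_label=_squash(full_label), binomial=binomial,
                   authority=authority, status=status, taxon_id=taxon_id)


@dataclass(frozen=True)
class Taxon:
    id: str
    rank: Rank
    parent_id: str | None
    reference_name_id: str
    synonym_name_ids: frozenset[str] = frozenset()
    vernacular_labels: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.reference_name_id in self.synonym_name_ids:
            raise ValueError(f"{self.id}: reference name listed among synonyms")


@dataclass
class TaxonomyGraph:
    """Referentially closed collection of taxa and their names."""

    taxa: dict[str, Taxon] = field(default_factory=dict)
    names: dict[str, ScientificName] = field(default_factory=dict)

    def validate(self) -> None:
        """Check referential closure, parent acyclicity and rank monotonicity."""
        for name in self.names.values():
            if name.taxon_id not in self.taxa:
                raise LoadError(f"name {name.id} references absent taxon {name.taxon_id}")
        for taxon in self.taxa.values():
            for nid in {taxon.reference_name_id, *taxon.synonym_name_ids}:
                if nid not in self.names:
                    raise LoadError(f"taxon {taxon.id} references absent name {nid}")
                if self.names[nid].taxon_id != taxon.id:
                    raise LoadError(f"name {nid} not owned by taxon {taxon.id}")
            if self.names[taxon.reference_name_id].status != "reference":
                raise LoadError(f"taxon {taxon.id}: reference name has synonym status")
            if taxon.parent_id is not None:
                parent = self.taxa.get(taxon.parent_id)
                if parent is None:
                    raise LoadError(f"taxon {taxon.id} references absent parent {taxon.parent_id}")
                if parent.rank >= taxon.rank:
                    raise LoadError(
                        f"taxon {taxon.id} ({taxon.rank.label}) under parent "
                        f"{parent.id} of rank {parent.rank.label}"
                    )
        # rank monotonicity along parent links already rules out cycles, but a
        # malformed graph could still loop among equal ids; walk defensively
        for taxon in self.taxa.values():
            seen = {taxon.id}
            current = taxon
            while current.parent_id is not None:
                if current.parent_id in seen:
                    raise LoadError(f"parent cycle through {current.parent_id}")
                seen.add(current.parent_id)
                current = self.taxa[current.parent_id]


@dataclass(frozen=True)
class CropUsage:
    """A crop usage (or usage category): a SKOS concept with French labels."""

    id: str
    pref_label: str
    alt_labels: frozenset[str] = frozenset()
    definition: str | None = None
    notes: tuple[tuple[str, str], ...] = ()  # (text, source)
    broader_id: str | None = None

    def __post_init__(self):
        if not self.pref_label.strip():
            raise ValueError(f"{self.id}: empty pref_label")


@dataclass
class UsageThesaurus:
    """Crop-usage concepts under the two top branches."""

    concepts: dict[str, CropUsage] = field(default_factory=dict)
    root_multiusages: str = "fcu:Multiusages"
    root_usages: str = "fcu:Usages_plantes_cultivees"

    def validate(self) -> None:
        roots = {self.root_multiusages, self.root_usages}
        for concept in self.concepts.values():
            if concept.id in roots:
                continue
            seen = {concept.id}
            current = concept
            while current.broader_id is not None:
                if current.broader_id in seen:
                    raise LoadError(f"broader cycle through {current.broader_id}")
                if current.broader_id in roots:
                    break
                nxt = self.concepts.get(current.broader_id)
                if nxt is None:
                    raise LoadError(
                        f"concept {concept.id}: broader chain hits absent {current.broader_id}"
                    )
                seen.add(nxt.id)
                current = nxt
            else:
                raise LoadError(f"concept {concept.id} reaches no top branch")

    def depth(self, usage_id: str) -> int:
        """Number of broader links from *usage_id* to its top branch root."""
        concept = self._get(usage_id)
        depth = 0
        roots = {self.root_multiusages, self.root_usages}
        while concept.broader_id is not None and concept.id not in roots:
            depth += 1
            if concept.broader_id in roots:
                break
            concept = self._get(concept.broader_id)
        return depth

    def _get(self, usage_id: str) -> CropUsage:
        try:
            return self.concepts[usage_id]
        except KeyError:
            raise MissingEntityError(f"unknown crop usage {usage_id!r}") from None


# ---------------------------------------------------------------------------
# Lookup operations


@dataclass(frozen=True)
class NameMatch:
    """Outcome of a tolerant scientific-name lookup.

    ``status`` is ``"match"``, ``"no_match"`` or ``"ambiguous"``. On a match,
    ``matched_status`` says whether the matched name is the taxon's reference
    name or a synonym. On ambiguity, ``candidates`` lists the
    (taxon_id, name_id) pairs of the decisive tier.
    """

    status: str
    taxon_id: str | None = None
    name_id: str | None = None
    matched_status: str | None = None
    candidates: tuple[tuple[str, str], ...] = ()

    def __bool__(self) -> bool:
        return self.status == "match"


def find_taxon_by_name(graph: TaxonomyGraph, query: str) -> NameMatch:
    """Tolerantly resolve a scientific-name string to a taxon.

    Matching is tiered, using the first tier with at least one hit:

    1. exact full label;
    2. binomial plus authority with the year stripped from both sides
       (catalogues often cite "L." where the register has "L., 1753");
    3. binomial only.

    A single hit is a match; several hits in the decisive tier yield an
    ambiguity result listing the candidates — never an exception.
    """
    query = _squash(query)
    if not query:
        return NameMatch(status="no_match")
    try:
        q_binomial, q_authority = parse_scientific_name(query)
    except InvalidNameError:
        return NameMatch(status="no_match")

    tier1, tier2, tier3 = [], [], []
    q_auth_stripped = strip_year(q_authority)
    for name in graph.names.values():
        if _squash(name.full_label) == query:
            tier1.append(name)
        if (
            q_auth_stripped is not None
            and name.binomial == q_binomial
            and strip_year(name.authority) == q_auth_stripped
        ):
            tier2.append(name)
        if name.binomial == q_binomial:
            tier3.append(name)

    for hits in (tier1, tier2, tier3):
        if not hits:
            continue
        hits = sorted(hits, key=lambda n: n.id)
        if len(hits) == 1:
            name = hits[0]
            return NameMatch(status="match", taxon_id=name.taxon_id, name_id=name.id,
                             matched_status=name.status)
        return NameMatch(
            status="ambiguous",
            candidates=tuple((n.taxon_id, n.id) for n in hits),
        )
    return NameMatch(status="no_match")


def reference_name(graph: TaxonomyGraph, taxon_id: str) -> ScientificName:
    """The unique reference (accepted/valid) name of a taxon."""
    taxon = graph.taxa.get(taxon_id)
    if taxon is None:
        raise MissingEntityError(f"unknown taxon {taxon_id!r}")
    name = graph.names.get(taxon.reference_name_id)
    if name is None or name.status != "reference":
        raise MissingEntityError(f"taxon {taxon_id!r} has no reference name")
    return name


def ancestors(graph: TaxonomyGraph, taxon_id: str) -> list[Taxon]:
    """Parent chain of a taxon, nearest first, strictly decreasing in specificity."""
    taxon = graph.taxa.get(taxon_id)
    if taxon is None:
        raise MissingEntityError(f"unknown taxon {taxon_id!r}")
    chain: list[Taxon] = []
    while taxon.parent_id is not None:
        taxon = graph.taxa[taxon.parent_id]
        chain.append(taxon)
    return chain


def is_crop_usage(thesaurus: UsageThesaurus, usage_id: str) -> bool:
    """True iff the concept is a *strict* descendant of the usages branch root.

    Curation only targets concepts below ``Usages_plantes_cultivees``; the
    multi-usage branch and the branch roots themselves are excluded.
    """
    concept = thesaurus._get(usage_id)
    while concept.broader_id is not None:
        if concept.broader_id == thesaurus.root_usages:
            return True
        if concept.broader_id == thesaurus.root_multiusages:
            return False
        concept = thesaurus._get(concept.broader_id)
    return False


def search_usages_by_label(thesaurus: UsageThesaurus, needle: str) -> list[CropUsage]:
    """Case-insensitive, accent-preserving substring search over pref labels.

    Results are ordered by concept id for determinism.
    """
    needle_cf = _nfc(needle).casefold()
    hits = [
        concept
        for concept in thesaurus.concepts.values()
        if needle_cf in _nfc(concept.pref_label).casefold()
    ]
    return sorted(hits, key=lambda c: c.id)


# ---------------------------------------------------------------------------
# Turtle subset I/O

TAXREFPROP = Namespace("http://taxref.mnhn.fr/lod/property/")


@dataclass(frozen=True)
class TaxonomyVocab:
    """Configurable property IRIs of the taxonomy Turtle subset."""

    has_rank: URIRef = TAXREFPROP.hasRank
    has_reference_name: URIRef = TAXREFPROP.hasReferenceName
    has_synonym: URIRef = TAXREFPROP.hasSynonym
    has_authority: URIRef = TAXREFPROP.hasAuthority
    vernacular_name: URIRef = TAXREFPROP.vernacularName


def _curie_map_with_vocab(curie_map: CurieMap | None) -> CurieMap:
    cm = curie_map or CurieMap.default()
    cm = CurieMap(bindings=dict(cm.bindings), joiners=dict(cm.joiners))
    cm.bindings.setdefault("taxrefprop", str(TAXREFPROP))
    return cm


def save_taxonomy(graph: TaxonomyGraph, path, curie_map: CurieMap | None = None,
                  vocab: TaxonomyVocab = TaxonomyVocab()) -> None:
    """Serialize a taxonomy to the Turtle subset (sorted, deterministic)."""
    cm = _curie_map_with_vocab(curie_map)
    g = Graph()
    for prefix, binding in sorted(cm.bindings.items()):
        g.bind(prefix, Namespace(binding + cm._joiner(prefix, "x")[:1] or binding))
    for taxon in sorted(graph.taxa.values(), key=lambda t: t.id):
        node = URIRef(cm.expand(taxon.id))
        g.add((node, RDF.type, OWL.Class))
        g.add((node, vocab.has_rank, Literal(taxon.rank.label)))
        if taxon.parent_id is not None:
            g.add((node, RDFS.subClassOf, URIRef(cm.expand(taxon.parent_id))))
        g.add((node, vocab.has_reference_name, URIRef(cm.expand(taxon.reference_name_id))))
        for nid in sorted(taxon.synonym_name_ids):
            g.add((node, vocab.has_synonym, URIRef(cm.expand(nid))))
        for label in sorted(taxon.vernacular_labels):
            g.add((node, vocab.vernacular_name, Literal(label, lang="fr")))
    for name in sorted(graph.names.values(), key=lambda n: n.id):
        node = URIRef(cm.expand(name.id))
        g.add((node, RDF.type, SKOS.Concept))
        g.add((node, RDFS.label, Literal(name.full_label)))
        g.add((node, SKOS.prefLabel, Literal(name.binomial)))
        if name.authority is not None:
            g.add((node, vocab.has_authority, Literal(name.authority)))
    g.serialize(destination=str(path), format="turtle")


def load_taxonomy(path, curie_map: CurieMap | None = None,
                  vocab: TaxonomyVocab = TaxonomyVocab()) -> TaxonomyGraph:
    """Load the taxonomy Turtle subset; unknown predicates are logged and ignored."""
    cm = _curie_map_with_vocab(curie_map)
    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as exc:  # rdflib raises assorted parser errors
        raise LoadError(f"cannot parse taxonomy file {path}: {exc}") from exc

    known_taxon_preds = {RDF.type, RDFS.subClassOf, RDFS.label, vocab.has_rank,
                         vocab.has_reference_name, vocab.has_synonym,
                         vocab.vernacular_name}
    known_name_preds = {RDF.type, RDFS.label, SKOS.prefLabel, vocab.has_authority}

    taxon_nodes = set(g.subjects(RDF.type, OWL.Class))
    name_nodes = set(g.subjects(RDF.type, SKOS.Concept))

    names: dict[str, ScientificName] = {}
    taxa: dict[str, Taxon] = {}

    # first pass: which taxon owns which name, and with which status
    owner: dict[URIRef, tuple[str, str]] = {}
    for t in taxon_nodes:
        tid = cm.contract(str(t))
        for n in g.objects(t, vocab.has_reference_name):
            owner[n] = (tid, "reference")
        for n in g.objects(t, vocab.has_synonym):
            owner[n] = (tid, "synonym")

    for n in sorted(name_nodes, key=str):
        nid = cm.contract(str(n))
        full = g.value(n, RDFS.label)
        if full is None:
            raise LoadError(f"name {nid} has no rdfs:label")
        if n not in owner:
            raise LoadError(f"name {nid} attached to no taxon")
        taxon_id, status = owner[n]
        authority = g.value(n, vocab.has_authority)
        binomial = g.value(n, SKOS.prefLabel)
        if binomial is None:
            binomial, authority = parse_scientific_name(str(full))
        names[nid] = ScientificName(
            id=nid, full_label=_squash(str(full)), binomial=_squash(str(binomial)),
            authority=_squash(str(authority)) if authority is not None else None,
            status=status, taxon_id=taxon_id)
        for pred in set(g.predicates(n)) - known_name_preds:
            logger.warning("ignoring unknown predicate %s on name %s", pred, nid)

    for t in sorted(taxon_nodes, key=str):
        tid = cm.contract(str(t))
        rank_lit = g.value(t, vocab.has_rank)
        if rank_lit is None:
            raise LoadError(f"taxon {tid} has no rank")
        ref = g.value(t, vocab.has_reference_name)
        if ref is None:
            raise LoadError(f"taxon {tid} has no reference name")
        parent = g.value(t, RDFS.subClassOf)
        taxa[tid] = Taxon(
            id=tid,
            rank=Rank.from_label(str(rank_lit)),
            parent_id=cm.contract(str(parent)) if parent is not None else None,
            reference_name_id=cm.contract(str(ref)),
            synonym_name_ids=frozenset(
                cm.contract(str(n)) for n in g.objects(t, vocab.has_synonym)
            ),
            vernacular_labels=frozenset(
                str(v) for v in g.objects(t, vocab.vernacular_name)
            ),
        )
        for pred in set(g.predicates(t)) - known_taxon_preds:
            logger.warning("ignoring unknown predicate %s on taxon %s", pred, tid)

    model = TaxonomyGraph(taxa=taxa, names=names)
    model.validate()
    return model


def save_thesaurus(thesaurus: UsageThesaurus, path, curie_map: CurieMap | None = None) -> None:
    """Serialize a usage thesaurus to the Turtle subset."""
    cm = curie_map or CurieMap.default()
    g = Graph()
    for prefix, binding in sorted(cm.bindings.items()):
        g.bind(prefix, Namespace(binding + cm._joiner(prefix, "x")[:1] or binding))
    for concept in sorted(thesaurus.concepts.values(), key=lambda c: c.id):
        node = URIRef(cm.expand(concept.id))
        g.add((node, RDF.type, SKOS.Concept))
        g.add((node, SKOS.prefLabel, Literal(concept.pref_label, lang="fr")))
        for alt in sorted(concept.alt_labels):
            g.add((node, SKOS.altLabel, Literal(alt, lang="fr")))
        if concept.definition:
            g.add((node, SKOS.definition, Literal(concept.definition, lang="fr")))
        for text, source in concept.notes:
            g.add((node, SKOS.note, Literal(f"{text} — {source}", lang="fr")))
        if concept.broader_id is not None:
            g.add((node, SKOS.broader, URIRef(cm.expand(concept.broader_id))))
    g.serialize(destination=str(path), format="turtle")


def load_thesaurus(path, curie_map: CurieMap | None = None,
                   root_multiusages: str = "fcu:Multiusages",
                   root_usages: str = "fcu:Usages_plantes_cultivees") -> UsageThesaurus:
    """Load the thesaurus Turtle subset."""
    cm = curie_map or CurieMap.default()
    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as exc:
        raise LoadError(f"cannot parse thesaurus file {path}: {exc}") from exc

    known = {RDF.type, SKOS.prefLabel, SKOS.altLabel, SKOS.definition, SKOS.note, SKOS.broader}
    concepts: dict[str, CropUsage] = {}
    for node in sorted(set(g.subjects(RDF.type, SKOS.Concept)), key=str):
        cid = cm.contract(str(node))
        pref = g.value(node, SKOS.prefLabel)
        if pref is None:
            raise LoadError(f"concept {cid} has no skos:prefLabel")
        broader = g.value(node, SKOS.broader)
        notes = []
        for note in sorted(g.objects(node, SKOS.note), key=str):
            text, _, source = str(note).rpartition(" — ")
            notes.append((text or str(note), source))
        definition = g.value(node, SKOS.definition)
        concepts[cid] = CropUsage(
            id=cid,
            pref_label=_squash(str(pref)),
            alt_labels=frozenset(str(a) for a in g.objects(node, SKOS.altLabel)),
            definition=str(definition) if definition is not None else None,
            notes=tuple(notes),
            broader_id=cm.contract(str(broader)) if broader is not None else None,
        )
        for pred in set(g.predicates(node)) - known:
            logger.warning("ignoring unknown predicate %s on concept %s", pred, cid)

    model = UsageThesaurus(concepts=concepts, root_multiusages=root_multiusages,
                           root_usages=root_usages)
    model.validate()
    return model


def load_graphs(taxonomy_path, thesaurus_path,
                curie_map: CurieMap | None = None) -> tuple[TaxonomyGraph, UsageThesaurus]:
    """Load both knowledge graphs from their Turtle-subset files."""
    return (load_taxonomy(taxonomy_path, curie_map=curie_map),
            load_thesaurus(thesaurus_path, curie_map=curie_map))
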