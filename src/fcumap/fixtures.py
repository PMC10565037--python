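"""Deterministic demo graphs and a seeded random generator.

``build_demo_taxonomy`` / ``build_demo_thesaurus`` / ``build_demo_mapping_set``
rebuild the worked carrot/chicory/tomato/grapevine mini-graphs used
throughout the documentation and tests: a small excerpt of the French
taxonomic register (two-level taxon/name model) and of the French crop-usage
thesaurus, plus the mapping set connecting them.

Ids printed by the upstream resources (``taxref:taxon/94503``,
``taxref:name/133744``, ``fcu:Carottes_potageres``, …) are reused verbatim so
examples read naturally; entities whose upstream ids are not public here
(the genus taxa, the gadecaei subspecies, the chicory/tomato/grapevine taxa,
and the authority of name/133744) carry synthetic ids/values marked with a
``demo-`` prefix or noted below — they are fixture choices, not upstream
facts.

``generate_random`` builds arbitrarily sized graphs and expert assertions
honouring every model invariant, for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .curation import ExpertAssertion
from .errors import ParameterError
from .graph_model import (CropUsage, Rank, ScientificName, Taxon, TaxonomyGraph,
                          UsageThesaurus)
from .mapping_core import (MappingSet, MappingSetMeta, compute_cardinality,
                           new_mapping)

__all__ = ["build_demo_taxonomy", "build_demo_thesaurus", "build_demo_mapping_set",
           "GeneratorParams", "generate_random"]


def _taxon(taxa, names, tid, rank, parent, ref_label, ref_id=None, synonyms=(),
           vernaculars=()):
    ref_id = ref_id or tid.replace("taxon/", "name/")
    names[ref_id] = ScientificName.from_label(ref_id, ref_label, "reference", tid)
    syn_ids = []
    for i, label in enumerate(synonyms):
        sid = f"{ref_id}-syn{i}"
        names[sid] = ScientificName.from_label(sid, label, "synonym", tid)
        syn_ids.append(sid)
    taxa[tid] = Taxon(id=tid, rank=rank, parent_id=parent, reference_name_id=ref_id,
                      synonym_name_ids=frozenset(syn_ids),
                      vernacular_labels=frozenset(vernaculars))


def build_demo_taxonomy() -> TaxonomyGraph:
    """The demo taxonomy: carrot, chicory, tomato and grapevine lineages.

    Taxon/name ids 94503 and 133744 are the upstream identifiers of *Daucus
    carota* and *D. carota* subsp. *sativus*; ids containing ``demo-`` are
    synthetic, as is the authority of name/133744.
    """
    taxa: dict[str, Taxon] = {}
    names: dict[str, ScientificName] = {}
    t = lambda *a, **k: _taxon(taxa, names, *a, **k)

    t("taxref:taxon/demo-daucus", Rank.GENUS, None, "Daucus L., 1753")
    t("taxref:taxon/94503", Rank.SPECIES, "taxref:taxon/demo-daucus",
      "Daucus carota L., 1753",
      synonyms=["Daucus communis Rouy & E.G.Camus, 1901"],
      vernaculars=["carotte", "carotte sauvage"])
    t("taxref:taxon/133744", Rank.SUBSPECIES, "taxref:taxon/94503",
      "Daucus carota subsp. sativus (Hoffm.) Schübl. & G.Martens, 1834",
      vernaculars=["carotte cultivée"])
    t("taxref:taxon/demo-gadecaei", Rank.SUBSPECIES, "taxref:taxon/94503",
      "Daucus carota subsp. gadecaei (Rouy & E.G.Camus) Heywood, 1968")

    t("taxref:taxon/demo-cichorium", Rank.GENUS, None, "Cichorium L., 1753")
    t("taxref:taxon/demo-cichorium-intybus", Rank.SPECIES, "taxref:taxon/demo-cichorium",
      "Cichorium intybus L., 1753", vernaculars=["chicorée"])
    t("taxref:taxon/demo-cichorium-foliosum", Rank.VARIETY,
      "taxref:taxon/demo-cichorium-intybus",
      "Cichorium intybus var. foliosum Hegi, 1928")

    t("taxref:taxon/demo-solanum", Rank.GENUS, None, "Solanum L., 1753")
    t("taxref:taxon/demo-solanum-lycopersicum", Rank.SPECIES, "taxref:taxon/demo-solanum",
      "Solanum lycopersicum L., 1753", vernaculars=["tomate"])
    t("taxref:taxon/demo-solanum-cerasiforme", Rank.VARIETY,
      "taxref:taxon/demo-solanum-lycopersicum",
      "Solanum lycopersicum var. cerasiforme (Alef.) Fosberg, 1955")

    t("taxref:taxon/demo-vitis", Rank.GENUS, None, "Vitis L., 1753")
    t("taxref:taxon/demo-vitis-vinifera", Rank.SPECIES, "taxref:taxon/demo-vitis",
      "Vitis vinifera L., 1753", vernaculars=["vigne"])

    graph = TaxonomyGraph(taxa=taxa, names=names)
    graph.validate()
    return graph


def build_demo_thesaurus() -> UsageThesaurus:
    """The demo crop-usage thesaurus: two top branches and the worked concepts.

    Depth positions of the demo concepts are fixture choices.
    """
    concepts: dict[str, CropUsage] = {}

    def add(cid, pref, broader=None, alts=(), definition=None, notes=()):
        concepts[cid] = CropUsage(id=cid, pref_label=pref, broader_id=broader,
                                  alt_labels=frozenset(alts), definition=definition,
                                  notes=tuple(notes))

    add("fcu:Multiusages", "multiusages")
    add("fcu:Usages_plantes_cultivees", "usages des plantes cultivées")

    add("fcu:carotte", "carotte", "fcu:Multiusages")
    add("fcu:tomate_multiusage", "plant de tomate", "fcu:Multiusages")

    add("fcu:Legumes", "légumes", "fcu:Usages_plantes_cultivees")
    add("fcu:Legumes_racines", "légumes racines", "fcu:Legumes")
    add("fcu:Carottes_potageres", "carotte potagère", "fcu:Legumes_racines",
        alts=["carotte cultivée"],
        definition="Carotte cultivée pour sa racine consommée comme légume.",
        notes=[("Plante potagère cultivée pour sa racine.",
                "Catalogue officiel des espèces et variétés")])
    add("fcu:Legumes_feuilles", "légumes feuilles", "fcu:Legumes")
    add("fcu:Chicorees_pain_de_sucre", "chicorée pain de sucre", "fcu:Legumes_feuilles",
        alts=["pain de sucre"])
    add("fcu:Legumes_fruits", "légumes fruits", "fcu:Legumes")
    add("fcu:Tomates", "tomate", "fcu:Legumes_fruits")

    add("fcu:Plantes_fourrageres", "plantes fourragères", "fcu:Usages_plantes_cultivees")
    add("fcu:Carottes_fourrageres", "carotte fourragère", "fcu:Plantes_fourrageres")

    add("fcu:Fruits", "fruits", "fcu:Usages_plantes_cultivees")
    add("fcu:Vignes", "vigne", "fcu:Fruits", alts=["vigne cultivée"])

    thesaurus = UsageThesaurus(concepts=concepts)
    thesaurus.validate()
    return thesaurus


def demo_meta() -> MappingSetMeta:
    """Set-level metadata used by the demo mapping set."""
    return MappingSetMeta(
        mapping_set_id="https://doi.org/10.57745/LVRFWJ",
        creator_id="https://ror.org/01pd2sz18",
        creator_label=("Mathématiques, Informatique et Statistique pour "
                       "l'Environnement et l'Agronomie"),
        subject_source="http://ontology.inrae.fr/frenchcropusage",
        subject_source_version="3.3",
        object_source="http://taxref.mnhn.fr/lod/taxref-ld",
        object_source_version="15.2",
        license="https://creativecommons.org/licenses/by/2.0/",
    )


def build_demo_mapping_set() -> MappingSet:
    """The demo mapping set: both carrot usages to the species and the
    cultivated subspecies (and their reference names), the invalid pair for
    the wild gadecaei subspecies, and the generic pair for sugarloaf chicory.

    All confidences are 1; cardinality is computed (the four carrot
    taxon-level mappings come out n:n)."""
    taxonomy = build_demo_taxonomy()
    thesaurus = build_demo_thesaurus()
    date = "2023-02-03T00:00:00Z"
    prov = dict(author_id="https://orcid.org/0000-0002-3076-5499",
                reviewer_id="https://orcid.org/0000-0002-5872-5034",
                mapping_date=date)

    def pair(usage, taxon_pred, name_pred, taxon_id, rule):
        from .curation import RULE_TEXTS
        ref = taxonomy.names[taxonomy.taxa[taxon_id].reference_name_id]
        usage_label = thesaurus.concepts[usage].pref_label
        return [
            new_mapping(usage, taxon_pred, taxon_id, 1.0, subject_label=usage_label,
                        object_label=ref.binomial, curation_rule_text=RULE_TEXTS[rule],
                        **prov),
            new_mapping(usage, name_pred, ref.id, 1.0, subject_label=usage_label,
                        object_label=ref.full_label, curation_rule_text=RULE_TEXTS[rule],
                        **prov),
        ]

    mappings = []
    for usage in ("fcu:Carottes_potageres", "fcu:Carottes_fourrageres"):
        mappings += pair(usage, "hasReferenceTaxon", "hasReferenceScientificName",
                         "taxref:taxon/94503", "CR_Geves")
        mappings += pair(usage, "hasReferenceTaxon", "hasReferenceScientificName",
                         "taxref:taxon/133744", "CR_C3PO_KB")
    mappings += pair("fcu:Carottes_potageres", "hasInvalidTaxon",
                     "hasInvalidScientificName", "taxref:taxon/demo-gadecaei",
                     "CR_Experts")
    mappings += pair("fcu:Chicorees_pain_de_sucre", "hasGenericTaxon",
                     "hasGenericScientificName", "taxref:taxon/demo-cichorium-foliosum",
                     "CR_Experts")
    return compute_cardinality(MappingSet(meta=demo_meta(), mappings=mappings))


# ---------------------------------------------------------------------------
# Random generator


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random graph/assertion generator.

    The defaults emulate a mid-sized curation campaign: a few dozen usages
    over a taxonomy a few times larger, about a fifth of taxa carrying a
    synonym (upstream registers list synonyms for a substantial minority of
    plant taxa), and a tenth of assertions naming an infraspecific taxon the
    register lacks, which exercises the parent-escalation branch.
    """

    n_usages: int = 30
    n_taxa: int = 120
    synonym_rate: float = 0.2
    missing_taxon_rate: float = 0.1
    max_depth: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_usages < 1 or self.n_taxa < 1 or self.max_depth < 1:
            raise ParameterError("counts must be >= 1")
        for rate in (self.synonym_rate, self.missing_taxon_rate):
            if not (0.0 <= rate <= 1.0):
                raise ParameterError("rates must be in [0, 1]")


_EPITHETS = ["carota", "sativus", "intybus", "foliosum", "vinifera", "cerasiforme",
             "communis", "annuus", "vulgaris", "officinalis", "album", "rubrum",
             "montanum", "pratense", "arvense", "campestre", "maritimum", "minor"]
_AUTHORS = ["L.", "Mill.", "Hegi", "Rouy", "Fosberg", "Heywood", "DC.", "Lam."]
_CHILD_RANKS = {Rank.GENUS: Rank.SPECIES, Rank.SPECIES: Rank.SUBSPECIES,
                Rank.SUBSPECIES: Rank.VARIETY, Rank.VARIETY: Rank.FORM,
                Rank.FORM: Rank.CULTIVAR}
_INFIX = {Rank.SUBSPECIES: "subsp.", Rank.VARIETY: "var.", Rank.FORM: "f.",
          Rank.CULTIVAR: "cv."}


def _random_authority(rng: random.Random) -> str:
    return f"{rng.choice(_AUTHORS)}, {rng.randint(1753, 1990)}"


def _letters(n: int) -> str:
    """Deterministic lowercase letter suffix (epithets must stay digit-free
    to parse as epithets)."""
    out = ""
    n += 1
    while n:
        n, rem = divmod(n - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def generate_random(params: GeneratorParams) -> tuple[TaxonomyGraph, UsageThesaurus,
                                                      list[ExpertAssertion]]:
    """Seeded random taxonomy, thesaurus and expert assertions.

    Reproducible: the same params yield identical structures. Binomials are
    unique by construction, so name lookup in the generated graph is never
    ambiguous; a ``synonym_rate`` fraction of non-genus taxa carry one
    synonym and a ``missing_taxon_rate`` fraction of assertions name an
    absent child of a present taxon (with the parent name supplied).
    """
    rng = random.Random(params.seed)

    taxa: dict[str, Taxon] = {}
    names: dict[str, ScientificName] = {}
    binomials: list[tuple[str, str]] = []  # (taxon_id, binomial)

    n_genera = max(1, params.n_taxa // 10)
    genus_labels = [f"Genus{_letters(i)}".capitalize() for i in range(n_genera)]
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"taxref:taxon/r{counter}"

    # genera first
    genus_ids = []
    for label in genus_labels:
        tid = new_id()
        _taxon(taxa, names, tid, Rank.GENUS, None, f"{label} {_random_authority(rng)}")
        genus_ids.append((tid, label))
    # then a forest of species and infraspecific taxa below them
    attachable: list[tuple[str, Rank, str]] = []  # (taxon_id, rank, binomial)
    used_epithets: set[str] = set()
    while len(taxa) < params.n_taxa:
        if attachable and rng.random() < 0.35:
            parent_id, parent_rank, parent_binomial = rng.choice(attachable)
            child_rank = _CHILD_RANKS.get(parent_rank)
            depth = parent_binomial.count(" ")  # rough proxy for tree depth
            if child_rank is None or depth >= params.max_depth + 1:
                continue
            epithet = f"{rng.choice(_EPITHETS)}{_letters(len(used_epithets))}"
            binomial = f"{parent_binomial} {_INFIX[child_rank]} {epithet}"
        else:
            parent_id, genus_label = rng.choice(genus_ids)
            child_rank = Rank.SPECIES
            epithet = f"{rng.choice(_EPITHETS)}{_letters(len(used_epithets))}"
            binomial = f"{genus_label} {epithet}"
        used_epithets.add(epithet)
        tid = new_id()
        synonyms = []
        if child_rank != Rank.GENUS and rng.random() < params.synonym_rate:
            syn_genus = rng.choice(genus_ids)[1]
            synonyms.append(f"{syn_genus} syn{_letters(len(used_epithets))} {_random_authority(rng)}")
        _taxon(taxa, names, tid, child_rank, parent_id,
               f"{binomial} {_random_authority(rng)}", synonyms=synonyms)
        binomials.append((tid, binomial))
        if child_rank in _CHILD_RANKS:
            attachable.append((tid, child_rank, binomial))

    graph = TaxonomyGraph(taxa=taxa, names=names)
    graph.validate()

    # thesaurus: two roots, then a random tree under the usages branch
    concepts: dict[str, CropUsage] = {}
    concepts["fcu:Multiusages"] = CropUsage(id="fcu:Multiusages", pref_label="multiusages")
    concepts["fcu:Usages_plantes_cultivees"] = CropUsage(
        id="fcu:Usages_plantes_cultivees", pref_label="usages des plantes cultivées")
    usage_ids = []
    for i in range(params.n_usages):
        cid = f"fcu:Usage_{i}"
        candidates = [c for c in usage_ids
                      if _thesaurus_depth(concepts, c) < params.max_depth]
        broader = rng.choice(candidates) if candidates and rng.random() < 0.6 \
            else "fcu:Usages_plantes_cultivees"
        concepts[cid] = CropUsage(id=cid, pref_label=f"usage {i}", broader_id=broader)
        usage_ids.append(cid)
    thesaurus = UsageThesaurus(concepts=concepts)
    thesaurus.validate()

    # expert assertions over the generated graphs
    assertions: list[ExpertAssertion] = []
    candidates = [(tid, b) for tid, b in binomials]
    for i, usage_id in enumerate(usage_ids):
        tid, binomial = rng.choice(candidates) if candidates else (None, None)
        if tid is None:
            break
        taxon = taxa[tid]
        ref = names[taxon.reference_name_id]
        if rng.random() < params.missing_taxon_rate and taxon.rank in _CHILD_RANKS:
            child_rank = _CHILD_RANKS[taxon.rank]
            missing = f"{binomial} {_INFIX[child_rank]} absens{_letters(i)}"
            assertions.append(ExpertAssertion(
                usage_id=usage_id, scientific_name_text=missing,
                parent_name_text=ref.full_label,
                reviewer_label="Reviewer R", author_label="Author A"))
        elif taxon.synonym_name_ids and rng.random() < 0.5:
            syn = names[sorted(taxon.synonym_name_ids)[0]]
            assertions.append(ExpertAssertion(
                usage_id=usage_id, scientific_name_text=syn.full_label,
                reviewer_label="Reviewer R", author_label="Author A"))
        else:
            assertions.append(ExpertAssertion(
                usage_id=usage_id, scientific_name_text=ref.full_label,
                reviewer_label="Reviewer R", author_label="Author A"))
    return graph, thesaurus, assertions


def _thesaurus_depth(concepts: dict[str, CropUsage], cid: str) -> int:
    depth = 0
    current = concepts[cid]
    while current.broader_id is not None and current.broader_id in concepts:
        depth += 1
        current = concepts[current.broader_id]
    return depth
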