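# fcumap

Aligning agricultural **crop-usage** vocabularies with biological
**taxonomies** is harder than it looks: a cultivated plant is named by what
it is *used for* (vegetable carrot vs fodder carrot), while a taxonomic
register names *taxa* placed at ranks and their regulated *scientific names*
(one reference — accepted/valid — name plus synonyms per taxon). Sources
disagree on authorities and dates ("Daucus carota", "Daucus carota L.",
"Daucus carota L., 1753"), vernacular names are ambiguous, and taxonomies
evolve. `fcumap` is a toolkit for curating, validating and publishing
high-confidence mappings between the two worlds, aimed at biodiversity
informaticians and agricultural data managers.

## What it provides

- **Graph models** for a two-level taxonomy (taxa as OWL classes with rank
  and parent; scientific names as SKOS concepts split into binomial +
  authority) and for a SKOS crop-usage thesaurus with two top branches,
  loaded from a Turtle subset. Name lookup is tiered and tolerant: exact
  full label, then binomial + year-stripped authority, then binomial only —
  ambiguity is a first-class result, never a silent pick.
- **A 22-property mapping vocabulary**: 10 annotation properties linking a
  crop usage to a taxon and 12 object properties linking it to a scientific
  name, organized in candidate / reference / generic / specific / invalid
  families with inverses and *companion* semantics (a name-level mapping
  requires the matching taxon-level mapping). The four invalid properties
  are negative mappings: they assert a correspondence should **not** exist.
- **Three executable curation rules** (catalogue record, knowledge-base
  record, expert assertion) that emit mappings only on unambiguous
  resolution, always at confidence 1, plus derivation of name-level mappings
  from taxon-level ones.
- **Validation** (13 coded checks: companion pairing, reference/synonym
  status, positive/invalid conflicts, duplicates, CURIE hygiene, publication
  policy) and **obsolescence diffing** against new graph versions.
- **SSSOM TSV I/O** in embedded-metadata mode ('#'-prefixed YAML header +
  tab-separated mappings) with automatic `mapping_cardinality` computation
  and byte-stable serialization.

## Worked example

```python
from fcumap import (GevesRecord, ExpertAssertion, apply_cr_geves,
                    apply_cr_experts, curate_batch, write_tsv)
from fcumap.fixtures import (build_demo_taxonomy, build_demo_thesaurus,
                             demo_meta)

taxonomy = build_demo_taxonomy()
thesaurus = build_demo_thesaurus()

# A catalogue row: vernacular name, usage category, scientific name.
record = GevesRecord(common_species="carotte", category="Potagère",
                     botanical_species="Daucus carota L.")
outcome = apply_cr_geves(record, thesaurus, taxonomy)
for m in outcome.mappings:
    print(m.subject_id, m.predicate_id, m.object_id, m.confidence)
```

prints

```
fcu:Carottes_potageres fcu:def/hasReferenceTaxon taxref:taxon/94503 1.0
fcu:Carottes_potageres fcu:def/hasReferenceScientificName taxref:name/94503 1.0
```

The vegetable-carrot usage resolved uniquely (the category token
disambiguates it from fodder carrot), and "Daucus carota L." matched the
register's "Daucus carota L., 1753" through the year-stripped tier — so the
rule emits the taxon-level mapping and its companion name-level mapping,
both at total confidence. An expert asserting the synonym "Daucus communis
Rouy & E.G.Camus, 1901" for fodder carrot instead yields **three** mappings
(reference taxon, reference name, and the matched synonym under the
synonymous-scientific-name property). Batch curation deduplicates, computes
cardinality (the demo's two carrot usages against the species and the
cultivated subspecies come out `n:n`) and serializes:

```python
mapping_set, skipped = curate_batch([record], thesaurus, taxonomy, demo_meta())
write_tsv(mapping_set, "carrot.sssom.tsv")
```

A CLI wraps the same operations (`fcumap fixtures export`, `fcumap validate`,
`fcumap curate`, `fcumap derive`, `fcumap cardinality`, `fcumap diff`).

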