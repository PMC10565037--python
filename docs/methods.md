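# Methods

## The two knowledge graphs

**Taxonomy.** The taxonomic side follows a strict separation of taxonomy and
nomenclature. A *taxon* is an OWL class at a rank, whose parent is the next
higher-ranked taxon; rank order is fixed and total:

    kingdom < phylum < class < order < family < genus < species
            < subspecies < variety < form < cultivar

The order below subspecies (variety < form < cultivar) follows botanical
convention; it matters because loading enforces that a parent's rank is
strictly less specific than its child's, which also rules out parent cycles.
Each taxon owns exactly one *reference* scientific name (the accepted name
in zoology, the valid name in botany) and any number of synonyms; a name is
a SKOS concept whose full label splits into *binomial* (epithets plus rank
infixes `subsp.`/`var.`/`f.`/`cv.`) and *authority* (author citation,
optional year).

**Crop-usage thesaurus.** The usage side is a SKOS scheme with French
preferred/alternative labels and two top branches: one for multi-usage
cultivated plants, one organizing plants by usage. Curation only targets
*strict* descendants of the usages branch; the branch roots and the
multi-usage branch are excluded (ambiguous by design).

Both models keep ids as opaque CURIE strings compared exactly after NFC
normalization; ids are never synthesized from labels. The Turtle loader
ignores unknown predicates with a logged warning (real dumps carry payload —
habitats, statuses — outside this scope) but treats dangling references as
fatal, naming the offending node.

## Name parsing and tolerant matching

`parse_scientific_name` scans tokens: genus, then an epithet (a lowercase
word directly after the genus or a rank infix). Infraspecific names may
interleave an authority before a deeper infix ("Cichorium intybus var.
foliosum **Hegi** f. cylindricum"), so the binomial extends through the
*last* infix+epithet pair; only what trails the final epithet is the
authority. Re-joining binomial and authority reproduces the input up to
whitespace normalization.

`find_taxon_by_name` is tiered, using the first tier with at least one hit:

1. exact full label;
2. binomial + authority with a trailing `, <4-digit year>` stripped from
   both sides (catalogues often cite "L." where the register has
   "L., 1753"); this tier only applies when the query carries an authority;
3. binomial only.

One hit is a match (reporting whether it hit a reference name or a synonym);
several hits in the decisive tier return an ambiguity value listing all
candidates. No-match and ambiguity are result values, not exceptions,
because the curation policy is *unique-or-skip*.

## The mapping vocabulary

22 properties in two layers. Ten annotation properties link a usage to a
taxon: the candidate property and its four specializations (reference,
generic, specific, invalid), each with an inverse running taxon→usage.
Twelve object properties link a usage to a scientific name: the same five
families with inverses, plus two synonymous properties without declared
inverses. Every usage→name property carries a *companion* annotation
property — the taxon-level assertion that must accompany it on the same
subject; the two synonymous properties take the reference-taxon property as
companion. The synonymous-vernacular property runs name→usage, opposite to
its siblings; it is stored with that direction and the same companion. The
four invalid-family properties are *negative*: under the open-world
assumption an absent mapping proves nothing, so incorrect correspondences
are asserted explicitly.

The registry's canonical CURIEs use the `ontofcu:` prefix; serialized
predicate ids use the published `fcu:def/<name>` spelling, and lookup
accepts either (plus the bare name). The full namespace behind the prefix is
configurable — a prefix map, defaulting to the vocabulary's definition
namespace — since only the compact forms are fixed.

## Curation rules

All rules share the publication policy: confidence is exactly 1 or nothing
is emitted (experts could not meaningfully grade partial confidence, so only
total-confidence mappings are published), and any ambiguity yields a
*skipped outcome* carrying a reason, never an exception or a guess.

- **CR_Geves** (catalogue record: common species / category / botanical
  species). Usage resolution is the one genuinely open design point: the
  rule matches the casefolded common-species string as a substring of
  pref/alt labels over strict descendants of the usages branch, narrows by
  category tokens when that keeps at least one candidate, then takes the
  unique deepest survivor (depth = broader-links to the branch root);
  equally deep survivors mean ambiguity, hence skip. The taxon comes from
  tolerant name lookup on the botanical species. Success emits the
  reference-taxon mapping and its companion reference-scientific-name
  mapping.
- **CR_C3PO_KB** (usage IRI + scientific-name IRI). The name IRI must
  resolve to a *reference* name — the rule's premise is that the source
  records reference names, so a synonym is a skip, not a silent correction —
  and the taxon is reached by following the reference-name link backwards.
  Two mappings.
- **CR_Experts** (free-text name assertion). Reference-name match → 2
  mappings; synonym match → 3 (the reference pair plus the matched synonym
  under the synonymous-scientific-name property — synonym mappings are only
  emitted for names an expert actually asserted, never bulk-derived for
  every synonym in the graph); no match but a resolvable parent name → 2
  mappings escalated to the generic properties. The parent name must be
  supplied by the caller, as the expert supplies it in practice; the rule
  does not guess parents from name morphology. A catalogue record resolving
  only at genus level does *not* escalate this way — CR_Geves skips instead
  (conservative: escalation is an expert decision).

`derive_name_mappings` maps each positive taxon-level category to its
name-level counterpart (reference→reference scientific name, etc.,
invalid→invalid) targeting the taxon's reference name, copying provenance
and confidence; an `existing` argument makes it a fixed point under
re-derivation.

## Cardinality

`mapping_cardinality` is a convenience field derivable from the set, so it
is computed, not curated: over positive (non-invalid) mappings only, and
separately within each predicate level — mixing levels would conflate a
usage's taxa with its names, and a negative mapping has no meaningful
degree. With `d_s` = distinct objects mapped from the subject and `d_o` =
distinct subjects mapped to the object (within the level), the value is
`1:1`, `1:n` (d_s>1), `n:1` (d_o>1) or `n:n`. `1:0`/`0:1` are accepted on
read but never produced (an existing mapping implies both degrees ≥ 1);
output is lowercase, uppercase accepted on read. The computation is
idempotent and order-insensitive, and tests recheck it against a
brute-force partner recount.

## Validation and diffing

Thirteen frozen issue codes (E1–E9 errors, W1–W4 warnings; catalogue in
`validation.py`). Notable choices: the companion check (E3) resolves "the
corresponding taxon" as the taxon owning the target name, and applies
uniformly — an invalid name-level mapping needs its invalid taxon-level
companion too; the branch restriction (W1) and the species-rank guideline
(W2, implemented as at-least-one-species-rank per subject, since a set
preserves no assertion order) are warnings, not errors, because they encode
curation focus rather than formal constraints; a confidence below 1 is a
warning at validation (W4) but blocks `check_publishable`. A score below 1
on a candidate-category mapping is likewise a warning, not an error — the
generic properties may carry automatic-alignment scores pending validation.

`find_obsolete` compares a set against new graph versions: missing subjects/
objects, and name-status flips (a reference name demoted to synonym suggests
swapping to the synonymous predicate, and vice versa) need no baseline;
rank-change detection needs the previous taxonomy, so the function takes an
optional `old_taxonomy` and skips that check without it.

## SSSOM TSV, embedded mode

Set metadata is '#'-prefixed YAML (two-space indentation, single-quoted
scalars) above a tab-separated table with a frozen column order; readers
accept any column order, missing optional columns, and unknown columns
(preserved verbatim on re-write). CURIE expansion is pure concatenation of
binding and local part, inserting a `/` when neither side carries a
separator (bindings are published without trailing separators while local
parts like `taxon/94503` expect one); the joiner is configurable per prefix.
Dates are ISO-8601 timestamps, date-only input promoted to midnight UTC;
confidence 1.0 renders as `1`. Writing is deterministic to the byte —
`write(read(write(S))) == write(S)` — which the test suite asserts on 100
seeded random sets. External-metadata mode and RDF serialization of mapping
sets are out of scope.

## Fixtures and the random generator

The demo graphs rebuild the carrot/chicory/tomato/grapevine worked examples;
upstream-printed ids (94503, 133744, the usage concept names) are reused
verbatim, everything else (`demo-` ids, the sativus authority, concept
depths) is a synthetic fixture choice flagged in the docstrings. One known
source discrepancy: the carrot name's date appears both as 1753 and 1758 in
the upstream documentation; the fixtures use 1753 (the majority reading).

`generate_random(GeneratorParams)` builds a seeded taxonomy forest (genera ≈
n_taxa/10, species and infraspecific taxa below, unique digit-free epithets
so lookup is never ambiguous), a usages-branch concept tree, and expert
assertions. Defaults emulate a mid-sized curation campaign: 30 usages over
120 taxa, `synonym_rate=0.2` (registers list synonyms for a substantial
minority of plant taxa), `missing_taxon_rate=0.1` (assertions naming an
infraspecific taxon the register lacks, exercising parent escalation),
`max_depth=4`. The generator does **not** emulate: shared binomials across
taxa (real homonyms exist; the ambiguity path is tested with constructed
fixtures instead), vernacular-label noise, non-Latin orthography, or
multi-synonym taxa — so passing property tests show internal consistency on
clean data, not robustness to every real-world register quirk. Problem
sizes in tests (100 random sets for round trips, 150–500 taxa for
graph-level properties) are the package's chosen balance between coverage
and a fast default suite.

## Known limitations

- Complex mappings (a usage fulfilled by a *combination* of taxa, e.g.
  rootstock + graft in viticulture) are not representable.
- Authority comparison strips years but does not normalize author
  abbreviations ("L." vs "Linnaeus").
- Usage resolution for catalogue records is label-substring based; it will
  skip (never mis-map) on vocabularies whose labels do not contain the
  vernacular name.
- Obsolescence diffing detects structural changes only; it does not track
  taxon merges/splits across different ids.
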