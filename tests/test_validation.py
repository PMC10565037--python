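"""Consistency checking, publication gate and obsolescence diffing."""

import random
from dataclasses import replace

import pytest

from fcumap import (CurieMap, Mapping, MappingSet, MappingSetMeta, check_publishable,
                    compute_cardinality, find_obsolete, new_mapping, validate)
from fcumap.fixtures import (build_demo_mapping_set, build_demo_taxonomy,
                             build_demo_thesaurus, demo_meta)
from fcumap.graph_model import Rank, TaxonomyGraph, UsageThesaurus


def _set(*mappings):
    return MappingSet(demo_meta(), list(mappings))


class TestValidate:
    def test_demo_set_passes_clean(self, demo_set, demo_taxonomy, demo_thesaurus):
        report = validate(demo_set, demo_taxonomy, demo_thesaurus)
        assert report.passed
        assert report.issues == []

    def test_unknown_predicate_e1(self, demo_taxonomy, demo_thesaurus):
        bad = Mapping("fcu:Carottes_potageres", "fcu:def/hasNoSuchThing", "t:1")
        report = validate(_set(bad), demo_taxonomy, demo_thesaurus)
        assert report.codes() == ["E1"]

    def test_type_mismatch_e2(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon", "taxref:taxon/94503")
        bad = replace(m, object_type="skos:Concept")
        report = validate(_set(bad), demo_taxonomy, demo_thesaurus)
        assert "E2" in report.codes()

    def test_missing_companion_e3(self, demo_taxonomy, demo_thesaurus):
        name_only = new_mapping("fcu:Carottes_potageres", "hasReferenceScientificName",
                                "taxref:name/94503")
        report = validate(_set(name_only), demo_taxonomy, demo_thesaurus)
        assert "E3" in report.codes()

    def test_companion_on_wrong_taxon_is_e3(self, demo_taxonomy, demo_thesaurus):
        """The companion must target the taxon that owns the mapped name."""
        pair = [
            new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                        "taxref:taxon/133744"),
            new_mapping("fcu:Carottes_potageres", "hasReferenceScientificName",
                        "taxref:name/94503"),
        ]
        report = validate(_set(*pair), demo_taxonomy, demo_thesaurus)
        assert "E3" in report.codes()

    def test_reference_name_mismatch_e4(self, demo_taxonomy, demo_thesaurus):
        pair = [
            new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                        "taxref:taxon/94503"),
            new_mapping("fcu:Carottes_potageres", "hasReferenceScientificName",
                        "taxref:name/94503-syn0"),  # a synonym, not the reference
        ]
        report = validate(_set(*pair), demo_taxonomy, demo_thesaurus)
        assert "E4" in report.codes()

    def test_synonym_mismatch_e5(self, demo_taxonomy, demo_thesaurus):
        pair = [
            new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                        "taxref:taxon/94503"),
            new_mapping("fcu:Carottes_potageres", "hasSynonymousScientificName",
                        "taxref:name/94503"),  # the reference, not a synonym
        ]
        report = validate(_set(*pair), demo_taxonomy, demo_thesaurus)
        assert "E5" in report.codes()

    def test_positive_invalid_conflict_e6(self, demo_taxonomy, demo_thesaurus):
        pair = [
            new_mapping("fcu:Carottes_potageres", "hasTaxon", "taxref:taxon/94503"),
            new_mapping("fcu:Carottes_potageres", "hasInvalidTaxon", "taxref:taxon/94503"),
        ]
        report = validate(_set(*pair), demo_taxonomy, demo_thesaurus)
        assert "E6" in report.codes()

    def test_duplicate_triple_e8(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon", "taxref:taxon/94503")
        report = validate(_set(m, m), demo_taxonomy, demo_thesaurus)
        assert "E8" in report.codes()

    def test_unbound_prefix_e9(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("mystery:usage", "hasReferenceTaxon", "taxref:taxon/94503")
        report = validate(_set(m), demo_taxonomy, demo_thesaurus)
        assert "E9" in report.codes()

    def test_multiusage_subject_w1(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:carotte", "hasReferenceTaxon", "taxref:taxon/94503")
        report = validate(_set(m), demo_taxonomy, demo_thesaurus)
        assert "W1" in report.codes()
        assert report.passed  # warning only

    def test_no_species_rank_reference_w2(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                        "taxref:taxon/133744")
        report = validate(_set(m), demo_taxonomy, demo_thesaurus)
        assert "W2" in report.codes()

    def test_stale_cardinality_w3(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon", "taxref:taxon/94503")
        stale = replace(m, mapping_cardinality="n:n")
        report = validate(_set(stale), demo_taxonomy, demo_thesaurus)
        assert "W3" in report.codes()

    def test_low_confidence_w4(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                        "taxref:taxon/94503", 0.9)
        report = validate(_set(m), demo_taxonomy, demo_thesaurus)
        assert "W4" in report.codes()

    def test_order_insensitive(self, demo_taxonomy, demo_thesaurus):
        mappings = [
            new_mapping("fcu:carotte", "hasReferenceTaxon", "taxref:taxon/94503", 0.5),
            new_mapping("fcu:Carottes_potageres", "hasReferenceScientificName",
                        "taxref:name/94503"),
            new_mapping("fcu:Carottes_potageres", "hasTaxon", "taxref:taxon/94503"),
            new_mapping("fcu:Carottes_potageres", "hasInvalidTaxon", "taxref:taxon/94503"),
        ]
        baseline = sorted(validate(_set(*mappings), demo_taxonomy, demo_thesaurus).codes())
        rng = random.Random(5)
        for _ in range(5):
            rng.shuffle(mappings)
            codes = sorted(validate(_set(*mappings), demo_taxonomy, demo_thesaurus).codes())
            assert codes == baseline


class TestCheckPublishable:
    def test_demo_set_publishable(self, demo_set, demo_taxonomy, demo_thesaurus):
        ok, _ = check_publishable(demo_set, demo_taxonomy, demo_thesaurus)
        assert ok

    def test_low_confidence_blocks_publication(self, demo_taxonomy, demo_thesaurus):
        m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                        "taxref:taxon/94503", 0.9)
        ok, _ = check_publishable(_set(m), demo_taxonomy, demo_thesaurus)
        assert not ok

    def test_empty_set_vacuously_publishable(self, demo_taxonomy, demo_thesaurus):
        ok, _ = check_publishable(_set(), demo_taxonomy, demo_thesaurus)
        assert ok


class TestFindObsolete:
    def test_identical_graphs_empty_report(self, demo_set, demo_taxonomy, demo_thesaurus):
        report = find_obsolete(demo_set, demo_taxonomy, demo_thesaurus,
                               old_taxonomy=demo_taxonomy)
        assert report.empty

    def test_deleted_taxon_flagged_object_missing(self, demo_set, demo_taxonomy,
                                                  demo_thesaurus):
        pruned = TaxonomyGraph(
            taxa={k: v for k, v in demo_taxonomy.taxa.items()
                  if k != "taxref:taxon/94503"},
            names=dict(demo_taxonomy.names))
        report = find_obsolete(demo_set, pruned, demo_thesaurus)
        reasons = {(m.object_id, reason) for m, reason in report.obsolete}
        assert ("taxref:taxon/94503", "object_missing") in reasons

    def test_deleted_usage_flagged_subject_missing(self, demo_set, demo_taxonomy,
                                                   demo_thesaurus):
        pruned = UsageThesaurus(
            concepts={k: v for k, v in demo_thesaurus.concepts.items()
                      if k != "fcu:Chicorees_pain_de_sucre"})
        report = find_obsolete(demo_set, demo_taxonomy, pruned)
        assert any(reason == "subject_missing" for _, reason in report.obsolete)

    def test_name_demoted_to_synonym_suggests_predicate_swap(self, demo_set,
                                                             demo_taxonomy,
                                                             demo_thesaurus):
        """A reference name demoted to synonym in the new version flips the
        suggested predicate to the synonymous one."""
        names = dict(demo_taxonomy.names)
        demoted = replace(names["taxref:name/133744"], status="synonym")
        promoted = replace(names["taxref:name/94503-syn0"], status="reference",
                           taxon_id="taxref:taxon/133744")
        names["taxref:name/133744"] = demoted
        names["taxref:name/94503-syn0"] = promoted
        new_taxonomy = TaxonomyGraph(taxa=dict(demo_taxonomy.taxa), names=names)
        report = find_obsolete(demo_set, new_taxonomy, demo_thesaurus)
        flagged = {m.object_id: reason for m, reason in report.obsolete}
        assert flagged.get("taxref:name/133744") == "name_status_changed"
        suggestions = {m.object_id: pred for m, pred in report.suggestions}
        assert suggestions["taxref:name/133744"] == "hasSynonymousScientificName"

    def test_rank_change_flagged_with_old_taxonomy(self, demo_set, demo_taxonomy,
                                                   demo_thesaurus):
        taxa = dict(demo_taxonomy.taxa)
        taxa["taxref:taxon/133744"] = replace(taxa["taxref:taxon/133744"],
                                              rank=Rank.VARIETY)
        new_taxonomy = TaxonomyGraph(taxa=taxa, names=dict(demo_taxonomy.names))
        report = find_obsolete(demo_set, new_taxonomy, demo_thesaurus,
                               old_taxonomy=demo_taxonomy)
        assert any(reason == "rank_changed" and m.object_id == "taxref:taxon/133744"
                   for m, reason in report.obsolete)
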