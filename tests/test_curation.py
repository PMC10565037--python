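"""Curation rules: worked carrot/chicory examples, branches, batching."""

import pytest

from fcumap import (C3poRecord, ExpertAssertion, GevesRecord, apply_cr_c3po,
                    apply_cr_experts, apply_cr_geves, curate_batch,
                    derive_name_mappings, new_mapping, registry, validate)
from fcumap.curation import read_records_csv, skipped_report_json
from fcumap.errors import WrongLevelError
from fcumap.fixtures import demo_meta


CARROT_GEVES = GevesRecord(common_species="carotte", category="Potagère",
                           botanical_species="Daucus carota L.")


class TestCrGeves:
    def test_carrot_record_two_mappings(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_geves(CARROT_GEVES, demo_thesaurus, demo_taxonomy)
        assert not outcome.skipped
        assert len(outcome.mappings) == 2
        taxon_m, name_m = outcome.mappings
        assert taxon_m.subject_id == "fcu:Carottes_potageres"
        assert taxon_m.predicate_id == "fcu:def/hasReferenceTaxon"
        assert taxon_m.object_id == "taxref:taxon/94503"
        assert name_m.predicate_id == "fcu:def/hasReferenceScientificName"
        assert name_m.object_id == "taxref:name/94503"
        assert all(m.confidence == 1 for m in outcome.mappings)
        assert all("CR_Geves" in m.curation_rule_text for m in outcome.mappings)

    def test_unknown_taxon_skipped(self, demo_taxonomy, demo_thesaurus):
        record = GevesRecord("carotte", "Potagère", "Zea mays L.")
        outcome = apply_cr_geves(record, demo_thesaurus, demo_taxonomy)
        assert outcome.skipped
        assert "taxon not found" in outcome.skip_reason

    def test_unknown_usage_skipped(self, demo_taxonomy, demo_thesaurus):
        record = GevesRecord("courgette", "Potagère", "Daucus carota L.")
        outcome = apply_cr_geves(record, demo_thesaurus, demo_taxonomy)
        assert outcome.skipped
        assert "usage not found" in outcome.skip_reason

    def test_equally_deep_duplicate_labels_are_ambiguous(self, demo_taxonomy):
        """Two equally specific usages carrying the same label must skip."""
        from fcumap.graph_model import CropUsage, UsageThesaurus
        concepts = {
            "fcu:Multiusages": CropUsage("fcu:Multiusages", "multiusages"),
            "fcu:Usages_plantes_cultivees": CropUsage("fcu:Usages_plantes_cultivees",
                                                      "usages des plantes cultivées"),
            "fcu:a": CropUsage("fcu:a", "carotte bizarre",
                               broader_id="fcu:Usages_plantes_cultivees"),
            "fcu:b": CropUsage("fcu:b", "carotte bizarre",
                               broader_id="fcu:Usages_plantes_cultivees"),
        }
        thesaurus = UsageThesaurus(concepts=concepts)
        # oracle: exhaustive label scan finds both concepts at equal depth
        matches = [c.id for c in concepts.values() if "carotte" in c.pref_label]
        assert len(matches) == 2
        outcome = apply_cr_geves(GevesRecord("carotte", "bizarre", "Daucus carota L."),
                                 thesaurus, demo_taxonomy)
        assert outcome.skipped
        assert "ambiguous usage" in outcome.skip_reason

    def test_category_disambiguates_the_two_carrot_usages(self, demo_taxonomy,
                                                          demo_thesaurus):
        outcome = apply_cr_geves(GevesRecord("carotte", "Fourragère", "Daucus carota L."),
                                 demo_thesaurus, demo_taxonomy)
        assert outcome.mappings[0].subject_id == "fcu:Carottes_fourrageres"


class TestCrC3po:
    def test_carrot_record_two_mappings(self, demo_taxonomy, demo_thesaurus):
        record = C3poRecord("fcu:Carottes_potageres", "taxref:name/133744")
        outcome = apply_cr_c3po(record, demo_thesaurus, demo_taxonomy)
        assert len(outcome.mappings) == 2
        assert outcome.mappings[0].object_id == "taxref:taxon/133744"
        assert outcome.mappings[1].object_id == "taxref:name/133744"
        assert all(m.confidence == 1 for m in outcome.mappings)

    def test_unknown_name_skipped(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_c3po(C3poRecord("fcu:Carottes_potageres", "taxref:name/nope"),
                                demo_thesaurus, demo_taxonomy)
        assert outcome.skipped

    def test_synonym_name_contradicts_premise(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_c3po(
            C3poRecord("fcu:Carottes_potageres", "taxref:name/94503-syn0"),
            demo_thesaurus, demo_taxonomy)
        assert outcome.skipped
        assert "synonym" in outcome.skip_reason


class TestCrExperts:
    def test_reference_branch_two_mappings(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_experts(
            ExpertAssertion("fcu:Carottes_fourrageres", "Daucus carota L., 1753"),
            demo_thesaurus, demo_taxonomy)
        assert len(outcome.mappings) == 2
        assert {m.predicate_id for m in outcome.mappings} == \
            {"fcu:def/hasReferenceTaxon", "fcu:def/hasReferenceScientificName"}

    def test_synonym_branch_three_mappings(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_experts(
            ExpertAssertion("fcu:Carottes_fourrageres",
                            "Daucus communis Rouy & E.G.Camus, 1901"),
            demo_thesaurus, demo_taxonomy)
        assert len(outcome.mappings) == 3
        synonym_m = outcome.mappings[2]
        assert synonym_m.predicate_id == "fcu:def/hasSynonymousScientificName"
        assert synonym_m.object_id == "taxref:name/94503-syn0"
        # the reference-name mapping still targets the taxon's reference name
        assert outcome.mappings[1].object_id == "taxref:name/94503"

    def test_parent_escalation_branch(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_experts(
            ExpertAssertion("fcu:Chicorees_pain_de_sucre",
                            "Cichorium intybus var. foliosum Hegi f. cylindricum",
                            parent_name_text="Cichorium intybus var. foliosum Hegi"),
            demo_thesaurus, demo_taxonomy)
        assert len(outcome.mappings) == 2
        assert {m.predicate_id for m in outcome.mappings} == \
            {"fcu:def/hasGenericTaxon", "fcu:def/hasGenericScientificName"}
        assert outcome.mappings[0].object_id == "taxref:taxon/demo-cichorium-foliosum"

    def test_nothing_resolves_skipped(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_experts(
            ExpertAssertion("fcu:Carottes_fourrageres", "Zea mays L."),
            demo_thesaurus, demo_taxonomy)
        assert outcome.skipped

    def test_provenance_copied(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_experts(
            ExpertAssertion("fcu:Carottes_fourrageres", "Daucus carota L., 1753",
                            reviewer_label="R. Eviewer", author_label="A. Uthor"),
            demo_thesaurus, demo_taxonomy)
        assert all(m.reviewer_label == "R. Eviewer" for m in outcome.mappings)
        assert all(m.author_label == "A. Uthor" for m in outcome.mappings)

    def test_random_assertions_never_raise_and_validate_clean(self, random_bundle):
        taxonomy, thesaurus, assertions = random_bundle
        for assertion in assertions:
            outcome = apply_cr_experts(assertion, thesaurus, taxonomy)
            assert outcome.skipped == (len(outcome.mappings) == 0)
            assert len(outcome.mappings) in (0, 2, 3)
            assert all(m.confidence == 1 for m in outcome.mappings)


class TestDeriveNameMappings:
    def test_reference_taxon_derives_reference_name(self, demo_taxonomy):
        taxon_m = new_mapping("fcu:Carottes_potageres", "hasReferenceTaxon",
                              "taxref:taxon/94503")
        derived = derive_name_mappings([taxon_m], demo_taxonomy)
        assert len(derived) == 1
        assert derived[0].predicate_id == "fcu:def/hasReferenceScientificName"
        assert derived[0].object_id == "taxref:name/94503"

    def test_invalid_taxon_derives_invalid_name(self, demo_taxonomy):
        taxon_m = new_mapping("fcu:Carottes_potageres", "hasInvalidTaxon",
                              "taxref:taxon/demo-gadecaei")
        derived = derive_name_mappings([taxon_m], demo_taxonomy)
        assert derived[0].predicate_id == "fcu:def/hasInvalidScientificName"

    def test_empty_input(self, demo_taxonomy):
        assert derive_name_mappings([], demo_taxonomy) == []

    def test_name_level_input_rejected(self, demo_taxonomy):
        name_m = new_mapping("fcu:a", "hasReferenceScientificName", "taxref:name/94503")
        with pytest.raises(WrongLevelError):
            derive_name_mappings([name_m], demo_taxonomy)

    def test_idempotent_fixed_point(self, demo_taxonomy, random_bundle):
        taxonomy, _, _ = random_bundle
        taxon_ids = sorted(taxonomy.taxa)[:10]
        taxon_ms = [new_mapping(f"fcu:Usage_{i}", "hasReferenceTaxon", tid)
                    for i, tid in enumerate(taxon_ids)]
        derived = derive_name_mappings(taxon_ms, taxonomy)
        again = derive_name_mappings(taxon_ms, taxonomy, existing=derived)
        assert again == []


class TestCurateBatch:
    def test_three_worked_records(self, demo_taxonomy, demo_thesaurus):
        """Catalogue + knowledge-base + expert records for carrot and chicory:
        six mappings, the two carrot rules pointing at different taxa kept
        distinct."""
        records = [
            CARROT_GEVES,
            C3poRecord("fcu:Carottes_potageres", "taxref:name/133744"),
            ExpertAssertion("fcu:Chicorees_pain_de_sucre",
                            "Cichorium intybus var. foliosum Hegi f. cylindricum",
                            parent_name_text="Cichorium intybus var. foliosum Hegi"),
        ]
        mapping_set, skipped = curate_batch(records, demo_thesaurus, demo_taxonomy,
                                            demo_meta())
        assert skipped == []
        assert len(mapping_set) == 6
        carrot_taxa = {m.object_id for m in mapping_set
                       if m.subject_id == "fcu:Carottes_potageres"
                       and m.object_type == "owl:Class"}
        assert carrot_taxa == {"taxref:taxon/94503", "taxref:taxon/133744"}
        assert all(m.confidence == 1 for m in mapping_set)
        report = validate(mapping_set, demo_taxonomy, demo_thesaurus)
        assert report.passed, report.to_text()

    def test_empty_batch(self, demo_taxonomy, demo_thesaurus):
        mapping_set, skipped = curate_batch([], demo_thesaurus, demo_taxonomy, demo_meta())
        assert len(mapping_set) == 0 and skipped == []

    def test_random_batch_validates_clean(self, random_bundle):
        taxonomy, thesaurus, assertions = random_bundle
        mapping_set, skipped = curate_batch(assertions, thesaurus, taxonomy, demo_meta())
        report = validate(mapping_set, taxonomy, thesaurus)
        assert report.passed, report.to_text()
        assert all(m.confidence == 1 for m in mapping_set)
        assert all(m.mapping_cardinality is not None for m in mapping_set
                   if m.predicate_id != "fcu:def/hasInvalidTaxon")


class TestRecordIO:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "geves.csv"
        path.write_text("common_species,category,botanical_species,cultivar_label\n"
                        "carotte,Potagère,\"Daucus carota L.\",Blanche de Küttingen\n",
                        encoding="utf-8")
        records = read_records_csv(path, "geves")
        assert records == [GevesRecord("carotte", "Potagère", "Daucus carota L.",
                                       "Blanche de Küttingen")]

    def test_skipped_report(self, demo_taxonomy, demo_thesaurus):
        outcome = apply_cr_geves(GevesRecord("courgette", "x", "Daucus carota L."),
                                 demo_thesaurus, demo_taxonomy)
        report = skipped_report_json([outcome])
        assert "CR_Geves" in report and "usage not found" in report
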