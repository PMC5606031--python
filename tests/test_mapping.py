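"""Legacy ODM-to-FHIR conversion: routing, loss accounting, determinism."""

import json
from decimal import Decimal

import pytest

from odmfhir import (
    LossLedger,
    MappingConfig,
    MappingConfigError,
    bind_code,
    convert_datatype,
    loss_report,
    map_event_data,
    map_study,
    map_study_def,
    map_subject,
    serialize_bundle,
    validate_bundle,
    validate_resource,
)
from odmfhir.mapping import CodeMapEntry, conservation_counts, map_form_def
from odmfhir.odm import ItemDef, ItemData, RangeCheck, StudyEventData

from conftest import small_study

EIGHT = {
    "CarePlan", "Patient", "ClinicalImpression", "EpisodeOfCare",
    "Encounter", "Questionnaire", "QuestionnaireResponse", "Observation",
}


class TestMapStudy:
    def test_full_coverage_yields_exactly_eight_resource_types(self, full_coverage):
        study, cfg = full_coverage
        bundle, _ = map_study(study, cfg)
        assert bundle.resource_types() == EIGHT

    def test_metadata_only_study_maps_to_metadata_resources_only(self, full_coverage):
        study, cfg = full_coverage
        bare = study.model_copy(deep=True)
        bare.subjects = []
        bundle, _ = map_study(bare, cfg)
        assert bundle.resource_types() == {"CarePlan", "Questionnaire"}

    def test_one_patient_and_impression_per_subject(self):
        study, cfg = small_study(4, n_subjects=4)
        bundle, _ = map_study(study, cfg)
        assert len(bundle.by_type("Patient")) == 4
        assert len(bundle.by_type("ClinicalImpression")) == 4

    def test_config_naming_unknown_oid_is_hard_error(self, bp):
        study, cfg = bp
        bad = cfg.model_copy(deep=True)
        bad.observation_groups.append("IG.NOPE")
        with pytest.raises(MappingConfigError, match="IG.NOPE"):
            map_study(study, bad)

    def test_invalid_leaf_value_dropped_with_ledger_entry(self, bp):
        study, cfg = bp
        broken = study.model_copy(deep=True)
        broken.subjects[0].events[0].forms[0].item_groups[0].items[0].value = "not-a-number"
        result = map_study(broken, cfg)
        counts = conservation_counts(broken, result)
        assert counts["dropped"] == 1
        assert counts["leaves"] == counts["answers"] + counts["observation"] + counts["dropped"]


class TestMapStudyDef:
    def test_one_activity_per_event(self, full_coverage):
        study, cfg = full_coverage
        plan = map_study_def(study, cfg)
        assert len(plan.attrs["activity"]) == len(study.metadata.study_event_defs)

    def test_unscheduled_event_marked_in_scheduled_field(self, full_coverage):
        study, cfg = full_coverage
        plan = map_study_def(study, cfg)
        by_event = dict(zip(study.metadata.study_event_defs, plan.attrs["activity"]))
        assert by_event["SE.ADHOC"]["detail"]["scheduled"] == "unscheduled"
        assert by_event["SE.SCREEN"]["detail"]["scheduled"] == "scheduled"

    def test_two_form_event_has_two_resolving_action_refs(self, full_coverage):
        study, cfg = full_coverage
        bundle, _ = map_study(study, cfg)
        plan = bundle.by_type("CarePlan")[0]
        screen = plan.attrs["activity"][0]  # SE.SCREEN has two forms
        assert len(screen["actionResulting"]) == 2
        for r in screen["actionResulting"]:
            rtype, rid = r["reference"].split("/")
            assert bundle.resource(rtype, rid) is not None


class TestMapFormDef:
    def test_group_and_question_counts_mirror_the_form(self):
        study, cfg = small_study(6, n_groups_per_form=2, n_items_per_group=3)
        form = next(iter(study.metadata.form_defs.values()))
        q = map_form_def(form, study.metadata, cfg)
        groups = q.attrs["group"]["group"]
        assert len(groups) == 2
        assert all(len(g["question"]) == 3 for g in groups)

    def test_code_list_item_question_carries_options(self, bp):
        study, cfg = bp
        q = map_form_def(study.metadata.form_defs["F.VITALS"], study.metadata, cfg)
        questions = {
            node["linkId"]: node for node in q.attrs["group"]["group"][0]["question"]
        }
        pos = questions["IT.BPPOS"]
        assert pos["type"] == "choice"
        assert {o["code"] for o in pos["option"]} == {"SITTING", "STANDING", "SUPINE"}

    @pytest.mark.parametrize("seed", range(10))
    def test_generated_questionnaires_always_valid(self, seed):
        study, cfg = small_study(seed)
        for form in study.metadata.form_defs.values():
            assert validate_resource(map_form_def(form, study.metadata, cfg)) == []


class TestMapSubject:
    def _demographic_study(self):
        study, cfg = small_study(8)
        # designate a date item and rewrite its values as a birth date
        dob_oid = next(
            oid for oid, idf in study.metadata.item_defs.items() if idf.datatype == "date"
        )
        cfg = cfg.model_copy(deep=True)
        cfg.demographic_items = {"birthDate": dob_oid}
        return study, cfg, dob_oid

    def test_designated_birth_date_passes_through(self):
        study, cfg, dob_oid = self._demographic_study()
        for _path, _s, _e, _f, _g, item in study.iter_leaves():
            if item.item_oid == dob_oid:
                item.value = "1970-01-01"
        patient, _ = map_subject(study.subjects[0], study, cfg, LossLedger())
        assert patient.attrs["birthDate"] == "1970-01-01"

    def test_unparseable_birth_date_left_empty_with_ledger_entry(self):
        study, cfg, dob_oid = self._demographic_study()
        for _path, _s, _e, _f, _g, item in study.iter_leaves():
            if item.item_oid == dob_oid:
                item.value = "01/01/1970"  # parses as no ISO date
        # keep referential validity: the raw stays a leaf; only the Patient
        # field is affected
        study.metadata.item_defs[dob_oid].datatype = "text"
        ledger = LossLedger()
        patient, _ = map_subject(study.subjects[0], study, cfg, ledger)
        assert "birthDate" not in patient.attrs
        assert any("unparseable" in e.note for e in ledger.entries)

    def test_subject_without_demographics_gets_ledger_entry(self, bp):
        study, cfg = bp
        ledger = LossLedger()
        patient, _ = map_subject(study.subjects[0], study, cfg, ledger)
        assert set(patient.attrs) == set()
        assert any("demographics unavailable" in e.note for e in ledger.entries)

    def test_every_impression_plan_resolves_to_the_careplan(self):
        study, cfg = small_study(10, n_subjects=3)
        bundle, _ = map_study(study, cfg)
        plan_id = bundle.by_type("CarePlan")[0].id
        impressions = bundle.by_type("ClinicalImpression")
        assert len(impressions) == 3
        for imp in impressions:
            assert imp.attrs["plan"][0]["reference"] == f"CarePlan/{plan_id}"


class TestMapEventData:
    def test_three_repeats_give_three_episodes(self):
        episodes = set()
        for rk in ("1", "2", "3"):
            evt = StudyEventData(study_event_oid="SE.1", repeat_key=rk)
            episode, _ = map_event_data(evt, "S001")
            episodes.add(episode.id)
        assert len(episodes) == 3

    def test_single_visit_event_yields_one_encounter(self, full_coverage):
        study, cfg = full_coverage
        bundle, _ = map_study(study, cfg)
        # P001: SE.SCREEN, SE.ADHOC, SE.DIARY x2; P002: SE.SCREEN -> 5 total
        assert len(bundle.by_type("Encounter")) == 5
        assert len(bundle.by_type("EpisodeOfCare")) == 5

    def test_each_encounter_references_its_subjects_patient(self, full_coverage):
        study, cfg = full_coverage
        bundle, _ = map_study(study, cfg)
        patients = {f"Patient/{p.id}" for p in bundle.by_type("Patient")}
        for enc in bundle.by_type("Encounter"):
            assert enc.attrs["patient"]["reference"] in patients


class TestWorkedExample:
    def test_single_two_component_observation_with_context(self, bp):
        study, cfg = bp
        bundle, _ = map_study(study, cfg)
        observations = bundle.by_type("Observation")
        assert len(observations) == 1
        obs = observations[0]
        values = {
            c["code"]["coding"][0]["code"]: c.get("valueQuantity", {})
            for c in obs.attrs["component"]
            if "valueQuantity" in c
        }
        assert values["8480-6"] == {"value": 119, "unit": "mmHg"}
        assert values["8462-4"] == {"value": 79, "unit": "mmHg"}
        assert obs.attrs["effectiveTime"].startswith("10:00")
        assert obs.attrs["bodySite"]["coding"][0]["code"] == "368208006"
        position = [
            c for c in obs.attrs["component"] if "valueCodeableConcept" in c
        ]
        assert position[0]["valueCodeableConcept"]["coding"][0]["code"] == "33586001"
        performer = obs.attrs["performer"][0]["reference"]
        practitioner = bundle.resource(*performer.split("/"))
        assert practitioner is not None
        assert "nurse" in practitioner.attrs["name"].lower()

    def test_leaf_conservation_on_worked_example(self, bp):
        study, cfg = bp
        result = map_study(study, cfg)
        counts = conservation_counts(study, result)
        assert counts["leaves"] == 6
        assert counts["leaves"] == counts["answers"] + counts["observation"] + counts["dropped"]


class TestConvertDatatype:
    def test_integer_and_boolean_conversion(self):
        idf = ItemDef(oid="IT.A", name="a", datatype="integer")
        assert convert_datatype(idf, 119, target="observation") == ("valueInteger", 119)
        idf = ItemDef(oid="IT.B", name="b", datatype="boolean")
        assert convert_datatype(idf, True, target="answer") == ("valueBoolean", True)

    def test_significant_digits_into_answer_logs_one_dropped_constraint(self):
        idf = ItemDef(oid="IT.F", name="f", datatype="float", significant_digits=1)
        ledger = LossLedger()
        key, value = convert_datatype(
            idf, Decimal("36.6"), target="answer", source_path="leaf", ledger=ledger
        )
        assert (key, value) == ("valueDecimal", 36.6)
        assert ledger.counts()["dropped-constraint"] == 1

    def test_range_checks_dropped_for_answers_kept_for_observations(self):
        idf = ItemDef(
            oid="IT.R", name="r", datatype="integer",
            range_checks=[RangeCheck(comparator="GE", bound=0)],
        )
        ledger = LossLedger()
        convert_datatype(idf, 5, target="answer", source_path="leaf", ledger=ledger)
        assert ledger.counts()["dropped-constraint"] == 1
        ledger = LossLedger()
        convert_datatype(idf, 5, target="observation", source_path="leaf", ledger=ledger)
        assert ledger.counts()["dropped-constraint"] == 0


class TestBindCode:
    def test_present_key_returns_mapped_concept(self):
        cm = {"K": CodeMapEntry(system="http://snomed.info/sct", code="1", display="One")}
        concept = bind_code("K", None, cm)
        assert concept.codings[0].code == "1"

    def test_absent_key_falls_back_to_text_only(self):
        concept = bind_code("K", "raw value", {})
        assert concept.codings == []
        assert concept.text == "raw value"

    def test_all_observations_have_nonempty_code(self):
        for seed in range(5):
            study, cfg = small_study(seed, fraction_observation_routed=1.0)
            bundle, _ = map_study(study, cfg)
            for obs in bundle.by_type("Observation"):
                code = obs.attrs["code"]
                assert code.get("coding") or code.get("text")


class TestLossLedger:
    def test_empty_ledger_report_has_zero_counts(self):
        report = json.loads(loss_report(LossLedger(), "json"))
        assert report["total"] == 0
        assert set(report["counts"].values()) == {0}

    def test_constructed_dropped_constraints_counted(self):
        ledger = LossLedger()
        for i in range(3):
            ledger.add(f"leaf{i}", "dropped-constraint", "range check lost")
        report = json.loads(loss_report(ledger, "json"))
        assert report["counts"]["dropped-constraint"] == 3

    def test_repurposed_entries_always_present_for_careplan_and_impression(self, bp):
        study, cfg = bp
        _, ledger = map_study(study, cfg)
        notes = [e.note for e in ledger.by_kind("repurposed-resource")]
        assert any("CarePlan" in n for n in notes)
        assert any("ClinicalImpression" in n for n in notes)

    def test_full_coverage_has_answer_path_dropped_constraint(self, full_coverage):
        study, cfg = full_coverage
        _, ledger = map_study(study, cfg)
        drops = ledger.by_kind("dropped-constraint")
        assert any("not representable in a question answer" in e.note for e in drops)

    def test_text_report_lists_all_kinds(self):
        ledger = LossLedger()
        ledger.add("a", "retyped", "x")
        text = loss_report(ledger, "text")
        assert "retyped: 1" in text and "total: 1" in text


class TestDeterminism:
    def test_identical_inputs_give_identical_bundle_and_report(self, full_coverage):
        study, cfg = full_coverage
        r1 = map_study(study, cfg)
        r2 = map_study(study, cfg)
        assert serialize_bundle(r1.bundle) == serialize_bundle(r2.bundle)
        assert loss_report(r1.ledger, "json") == loss_report(r2.ledger, "json")

    def test_rerun_ledger_is_identical(self, bp):
        study, cfg = bp
        assert map_study(study, cfg).ledger == map_study(study, cfg).ledger


@pytest.mark.parametrize("seed", range(8))
def test_conversion_conserves_every_leaf(seed):
    """answers + observation contributions + dropped-leaf entries = leaves."""
    study, cfg = small_study(seed)
    result = map_study(study, cfg)
    counts = conservation_counts(study, result)
    assert counts["leaves"] == counts["answers"] + counts["observation"] + counts["dropped"]
    assert validate_bundle(result.bundle) == []
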