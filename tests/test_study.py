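"""Native ClinicalStudyPlan / ClinicalStudyData: builders and validators."""

import copy
import random

import pytest

from odmfhir import (
    InvestigationMixError,
    MappingConfig,
    ProtocolMetaError,
    build_data,
    build_native_bundle,
    build_plan,
    validate_bundle,
    validate_data,
    validate_plan,
)
from odmfhir.study import (
    ClinicalStudyData,
    ClinicalStudyPlan,
    Goal,
    Investigations,
    Period,
    PlanActivity,
    StatusHistoryEntry,
    StudyEvent,
    Visit,
)

from conftest import small_study


class TestBuildPlan:
    def test_one_activity_per_event_with_status(self, full_coverage, protocol_meta):
        study, cfg = full_coverage
        plan = build_plan(study, protocol_meta, cfg)
        assert plan.status == "active"
        assert len(plan.activity) == len(study.metadata.study_event_defs)

    def test_goals_keep_their_three_sub_attributes(self, full_coverage, protocol_meta):
        study, cfg = full_coverage
        plan = build_plan(study, protocol_meta, cfg)
        assert len(plan.goal) == 2
        for g in plan.goal:
            assert g.outcome and g.metric and g.timepoint

    def test_missing_status_is_hard_error(self, full_coverage, protocol_meta):
        study, cfg = full_coverage
        meta = {k: v for k, v in protocol_meta.items() if k != "status"}
        with pytest.raises(ProtocolMetaError, match="status"):
            build_plan(study, meta, cfg)

    def test_observation_routed_groups_become_activity_details(
        self, full_coverage, protocol_meta
    ):
        study, cfg = full_coverage
        plan = build_plan(study, protocol_meta, cfg)
        details = [d for a in plan.activity for d in a.detail]
        assert details, "observation-routed groups should yield detail entries"
        assert all(d.category == {"text": "observation"} for d in details)

    @pytest.mark.parametrize("seed", range(10))
    def test_built_plans_always_validate(self, seed, protocol_meta):
        study, cfg = small_study(seed)
        assert validate_plan(build_plan(study, protocol_meta, cfg)) == []


class TestValidatePlan:
    def test_missing_status_is_one_violation_on_status(self, protocol_meta):
        plan = ClinicalStudyPlan(identifier="X")
        violations = validate_plan(plan)
        assert len(violations) == 1
        assert violations[0].path == "status"

    def test_minimal_plan_with_identifier_and_status_is_valid(self):
        assert validate_plan(ClinicalStudyPlan(identifier="X", status="active")) == []

    def test_incomplete_goal_and_empty_activity_flagged(self):
        plan = ClinicalStudyPlan(
            status="active",
            goal=[Goal(outcome="only outcome")],
            activity=[PlanActivity()],
            sample_size=0,
        )
        paths = {v.path for v in validate_plan(plan)}
        assert "goal[0].metric" in paths and "goal[0].timepoint" in paths
        assert "activity[0]" in paths
        assert "sampleSize" in paths

    def test_random_field_deletions_agree_with_brute_force_walker(
        self, full_coverage, protocol_meta
    ):
        """Oracle: independently recount invariant breaches after deleting
        random fields from a valid plan."""
        study, cfg = full_coverage
        base = build_plan(study, protocol_meta, cfg)
        rng = random.Random(7)
        fields = [
            "status", "sample_size", "goal", "activity", "title", "sponsor",
            "description", "registration_date", "investigator",
        ]
        for _ in range(200):
            plan = copy.deepcopy(base)
            for name in rng.sample(fields, k=rng.randint(0, 4)):
                setattr(plan, name, None if not isinstance(getattr(plan, name), list) else [])
            if rng.random() < 0.3 and plan.goal:
                plan.goal[0].metric = None
            if rng.random() < 0.3:
                plan.sample_size = rng.choice([0, -5])
            if rng.random() < 0.3 and plan.activity:
                plan.activity[0].action_resulting = []
                plan.activity[0].detail = []

            expected = 0
            expected += not plan.status
            for g in plan.goal:
                expected += sum(
                    not getattr(g, p) for p in ("outcome", "metric", "timepoint")
                )
            expected += plan.sample_size is not None and plan.sample_size <= 0
            for a in plan.activity:
                expected += not a.detail and not a.action_resulting
            assert len(validate_plan(plan)) == expected


class TestBuildData:
    def test_two_events_one_visit_each(self, protocol_meta):
        study, _ = small_study(3, n_subjects=1, n_events=2)
        cfg = MappingConfig()  # everything answer-routed: homogeneous visits
        plan = build_plan(study, protocol_meta, cfg)
        result = build_data(study, plan, cfg, study.subjects[0].subject_key)
        assert len(result.data.event) == 2
        assert sum(len(e.visit) for e in result.data.event) == 2

    def test_worked_example_visit_holds_observation_references_only(
        self, bp, protocol_meta
    ):
        study, cfg = bp
        plan = build_plan(study, protocol_meta, cfg)
        result = build_data(study, plan, cfg, "SUBJ001")
        visits = [v for e in result.data.event for v in e.visit]
        assert len(visits) == 1
        inv = visits[0].investigations
        assert inv.kinds_present() == ["observation"]
        assert len(inv.observation) == 1  # the single two-component Observation

    def test_mixed_visit_is_hard_error_naming_the_visit(
        self, full_coverage, protocol_meta
    ):
        study, cfg = full_coverage  # SE.SCREEN mixes routing by construction
        plan = build_plan(study, protocol_meta, cfg)
        with pytest.raises(InvestigationMixError, match="SE.SCREEN"):
            build_data(study, plan, cfg, "P001")

    def test_repeating_event_groups_visits_under_one_event(
        self, full_coverage, protocol_meta
    ):
        study, _ = full_coverage
        cfg = MappingConfig()  # all answers: homogeneous
        plan = build_plan(study, protocol_meta, cfg)
        result = build_data(study, plan, cfg, "P001")
        by_type = {e.type["text"]: e for e in result.data.event}
        assert len(by_type["Diary"].visit) == 2

    def test_native_path_repurposes_no_resource(self, bp, protocol_meta):
        study, cfg = bp
        plan = build_plan(study, protocol_meta, cfg)
        result = build_data(study, plan, cfg, "SUBJ001")
        assert result.ledger.by_kind("repurposed-resource") == []

    def test_native_bundle_patient_references_resolve(self, protocol_meta):
        study, _ = small_study(5, fraction_observation_routed=0.0)
        cfg = MappingConfig()
        bundle, _ = build_native_bundle(study, protocol_meta, cfg)
        assert validate_bundle(bundle) == []
        for csd in bundle.by_type("ClinicalStudyData"):
            rtype, rid = csd.attrs["patient"]["reference"].split("/")
            assert bundle.resource(rtype, rid) is not None


def _valid_data():
    return ClinicalStudyData(
        identifier="D1",
        patient={"reference": "Patient/p-1"},
        status="finished",
        event=[
            StudyEvent(
                status="finished",
                visit=[
                    Visit(
                        scheduled="planned",
                        investigations=Investigations(
                            questionnaire_response={"reference": "QuestionnaireResponse/r-1"}
                        ),
                    )
                ],
            )
        ],
    )


class TestValidateData:
    def test_valid_instance_passes(self):
        assert validate_data(_valid_data()) == []

    def test_missing_patient_is_a_violation(self):
        d = _valid_data()
        d.patient = None
        assert any(v.path == "patient" for v in validate_data(d))

    def test_visit_with_two_investigation_kinds_is_one_choice_violation(self):
        d = _valid_data()
        d.event[0].visit[0].investigations.observation = [
            {"reference": "Observation/o-1"}
        ]
        violations = validate_data(d)
        assert len(violations) == 1
        assert "investigations" in violations[0].path

    def test_visit_with_no_investigations_violates_the_choice(self):
        d = _valid_data()
        d.event[0].visit[0].investigations = Investigations()
        assert len(validate_data(d)) == 1

    def test_overlapping_status_history_periods_flagged(self):
        d = _valid_data()
        d.status_history = [
            StatusHistoryEntry(
                status="planned", period=Period(start="2016-01-01", end="2016-03-01")
            ),
            StatusHistoryEntry(
                status="in-progress", period=Period(start="2016-02-01", end="2016-04-01")
            ),
        ]
        violations = validate_data(d)
        assert len(violations) == 1
        assert "overlaps" in violations[0].message

    def test_only_last_status_period_may_be_open_ended(self):
        d = _valid_data()
        d.status_history = [
            StatusHistoryEntry(status="planned", period=Period(start="2016-01-01")),
            StatusHistoryEntry(
                status="finished", period=Period(start="2016-02-01", end="2016-03-01")
            ),
        ]
        assert any("open-ended" in v.message for v in validate_data(d))

    def test_unknown_visit_schedule_and_event_status_flagged(self):
        d = _valid_data()
        d.event[0].status = "meandering"
        d.event[0].visit[0].scheduled = "sometimes"
        paths = {v.path for v in validate_data(d)}
        assert "event[0].status" in paths
        assert "event[0].visit[0].scheduled" in paths

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_native_builds_always_satisfy_the_choice_rule(
        self, seed, fraction, protocol_meta
    ):
        """Sweep: homogeneous routing produces valid data resources."""
        study, gen_cfg = small_study(seed, fraction_observation_routed=fraction)
        cfg = (
            gen_cfg.model_copy(
                deep=True,
                update={
                    "observation_groups": sorted(study.metadata.item_group_defs)
                },
            )
            if fraction == 1.0
            else MappingConfig(code_map=gen_cfg.code_map)
        )
        plan = build_plan(study, protocol_meta, cfg)
        bundle, _ = build_native_bundle(study, protocol_meta, cfg)
        for subj in study.subjects:
            result = build_data(study, plan, cfg, subj.subject_key)
            assert validate_data(result.data, bundle) == []
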