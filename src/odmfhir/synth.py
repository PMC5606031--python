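"""Seeded synthetic ODM studies and the two fixed fixtures.

The generator emulates the structural shape of electronic-data-capture
exports — the Study → Subject → StudyEvent → Form → ItemGroup → Item
hierarchy with OID cross-references, code lists, range checks, measurement
units, and scheduled/unscheduled events — not epidemiological realism.
Generated values are always valid against their item definitions; invalid-
value cases are constructed explicitly in tests, never sampled, so that
conversion tests stay focused on routing and loss accounting.

A single integer seed drives one private ``random.Random``; no global
random state is touched, and a fixed seed reproduces the study (and its
mapping configuration) byte for byte.

Two fixed fixtures accompany the generator:

* :func:`bp_fixture` — the blood-pressure worked example: systolic
  119 mmHg / diastolic 79 mmHg captured in one visit together with its
  context (measured at 10:00 by a nurse, left upper arm, sitting), routed
  to a single two-component Observation with SNOMED CT / LOINC bindings.
* :func:`full_coverage_fixture` — a compact study exercising every mapping
  rule: scheduled, unscheduled and repeating events, grouped observation-
  and answer-routed items, a code-list item, and a range-checked float on
  the answer path (which the answer node cannot carry, hence a guaranteed
  dropped-constraint ledger entry).
"""

from __future__ import annotations

import random
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .fhir import LOINC_URI, SNOMED_URI
from .mapping import CodeMapEntry, MappingConfig
from .odm import (
    CodeList,
    CodeListItem,
    FormData,
    FormDef,
    ItemData,
    ItemDef,
    ItemGroupData,
    ItemGroupDef,
    MetaDataVersion,
    OdmStudy,
    RangeCheck,
    StudyEventData,
    StudyEventDef,
    SubjectData,
)

_DATATYPE_CYCLE = ("integer", "float", "text", "date", "boolean", "time", "datetime")
_WORDS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")
_UNITS = ("mmHg", "kg", "cm", "bpm", "mg/dL")


class GeneratorConfig(BaseModel):
    """Shape and routing parameters for one synthetic study."""

    seed: int = 0
    n_subjects: int = Field(default=3, ge=1)
    n_events: int = Field(default=2, ge=1)
    n_forms_per_event: int = Field(default=2, ge=1)
    n_groups_per_form: int = Field(default=2, ge=1)
    n_items_per_group: int = Field(default=3, ge=1)
    fraction_observation_routed: float = Field(default=0.4, ge=0.0, le=1.0)
    fraction_unscheduled_events: float = Field(default=0.2, ge=0.0, le=1.0)
    include_code_lists: bool = True
    include_range_checks: bool = True

    @model_validator(mode="after")
    def _sane(self) -> "GeneratorConfig":
        return self


def _value_for(rng: random.Random, idf: ItemDef, code_lists: dict[str, CodeList]) -> str:
    if idf.code_list_oid is not None:
        return rng.choice(code_lists[idf.code_list_oid].coded_values())
    dt = idf.datatype
    if dt == "integer":
        return str(rng.randint(0, 200))
    if dt == "float":
        return f"{rng.uniform(0, 200):.1f}"
    if dt == "text":
        return " ".join(rng.choice(_WORDS) for _ in range(2))
    if dt == "date":
        return f"20{rng.randint(10, 20):02d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    if dt == "time":
        return f"{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}:00"
    if dt == "datetime":
        return (
            f"20{rng.randint(10, 20):02d}-{rng.randint(1, 12):02d}-"
            f"{rng.randint(1, 28):02d}T{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}:00"
        )
    return rng.choice(("true", "false"))


def generate_study(cfg: GeneratorConfig) -> tuple[OdmStudy, MappingConfig]:
    """Deterministically generate a referentially intact study plus a
    routing configuration marking the requested fraction of item groups
    for Observation."""
    rng = random.Random(cfg.seed)
    md = MetaDataVersion(oid="MDV.1", name="Synthetic metadata")
    observation_groups: list[str] = []
    code_map: dict[str, CodeMapEntry] = {}

    item_counter = 0
    for e in range(1, cfg.n_events + 1):
        event_oid = f"SE.{e}"
        form_oids = []
        for f in range(1, cfg.n_forms_per_event + 1):
            form_oid = f"F.{e}.{f}"
            form_oids.append(form_oid)
            group_oids = []
            for g in range(1, cfg.n_groups_per_form + 1):
                group_oid = f"IG.{e}.{f}.{g}"
                group_oids.append(group_oid)
                item_oids = []
                for _ in range(cfg.n_items_per_group):
                    item_counter += 1
                    item_oid = f"IT.{item_counter}"
                    item_oids.append(item_oid)
                    datatype = _DATATYPE_CYCLE[(item_counter - 1) % len(_DATATYPE_CYCLE)]
                    code_list_oid = None
                    if (
                        cfg.include_code_lists
                        and datatype == "text"
                        and item_counter % 2 == 0
                    ):
                        code_list_oid = f"CL.{item_oid}"
                        md.code_lists[code_list_oid] = CodeList(
                            oid=code_list_oid,
                            name=f"Code list for {item_oid}",
                            datatype="text",
                            items=[
                                CodeListItem(coded_value=f"C{k}", decode=f"Choice {k}")
                                for k in range(1, 4)
                            ],
                        )
                    checks = []
                    unit = None
                    if datatype in ("integer", "float"):
                        unit = _UNITS[item_counter % len(_UNITS)]
                        if cfg.include_range_checks and item_counter % 2 == 1:
                            checks = [
                                RangeCheck(comparator="GE", bound=0),
                                RangeCheck(comparator="LE", bound=500),
                            ]
                    md.item_defs[item_oid] = ItemDef(
                        oid=item_oid,
                        name=f"Item {item_counter}",
                        question=f"Question {item_counter}?",
                        datatype=datatype,
                        measurement_unit=unit,
                        range_checks=checks,
                        code_list_oid=code_list_oid,
                    )
                    # bind every other observation-eligible item to a local code
                    if item_counter % 3 == 0:
                        code_map[item_oid] = CodeMapEntry(
                            system="http://example.org/local-codes",
                            code=item_oid,
                            display=f"Concept {item_counter}",
                        )
                md.item_group_defs[group_oid] = ItemGroupDef(
                    oid=group_oid, name=f"Group {group_oid}", item_refs=item_oids
                )
                if rng.random() < cfg.fraction_observation_routed:
                    observation_groups.append(group_oid)
            md.form_defs[form_oid] = FormDef(
                oid=form_oid, name=f"Form {form_oid}", item_group_refs=group_oids
            )
        md.study_event_defs[event_oid] = StudyEventDef(
            oid=event_oid,
            name=f"Event {e}",
            event_type=(
                "unscheduled"
                if rng.random() < cfg.fraction_unscheduled_events
                else "scheduled"
            ),
            form_refs=form_oids,
        )

    study = OdmStudy(
        study_oid=f"ST.SYN.{cfg.seed}",
        study_name=f"Synthetic study {cfg.seed}",
        protocol_name=f"Protocol SYN-{cfg.seed}",
        metadata=md,
    )
    for s in range(1, cfg.n_subjects + 1):
        subj = SubjectData(subject_key=f"S{s:03d}")
        for sed in md.study_event_defs.values():
            evt = StudyEventData(study_event_oid=sed.oid, repeat_key="1")
            for form_oid in sed.form_refs:
                fd = md.form_defs[form_oid]
                form = FormData(form_oid=form_oid)
                for group_oid in fd.item_group_refs:
                    igd = md.item_group_defs[group_oid]
                    grp = ItemGroupData(item_group_oid=group_oid)
                    for item_oid in igd.item_refs:
                        idf = md.item_defs[item_oid]
                        grp.items.append(
                            ItemData(
                                item_oid=item_oid,
                                value=_value_for(rng, idf, md.code_lists),
                            )
                        )
                    form.item_groups.append(grp)
                evt.forms.append(form)
            subj.events.append(evt)
        study.subjects.append(subj)

    mapping_cfg = MappingConfig(
        observation_groups=observation_groups,
        code_map=code_map,
    )
    return study, mapping_cfg


# ---------------------------------------------------------------------------
# Fixed fixtures
# ---------------------------------------------------------------------------


def bp_fixture() -> tuple[OdmStudy, MappingConfig]:
    """The blood-pressure worked example.

    One subject, one scheduled visit, one vital-signs form whose BP group
    holds the two measurements (systolic 119, diastolic 79, mmHg) plus the
    contextual items: measurement time 10:00, performer role nurse, body
    site left upper arm, patient position sitting.  The routing config
    sends the group to a single Observation whose components carry the two
    pressures (LOINC-coded under the blood-pressure panel code) and whose
    context lands natively: bodySite and position as SNOMED CT concepts,
    the nurse as a referenced Practitioner, the time as the effective time.
    """
    md = MetaDataVersion(oid="MDV.BP", name="Cardiovascular study metadata")
    md.code_lists["CL.POSITION"] = CodeList(
        oid="CL.POSITION",
        name="Body position",
        items=[
            CodeListItem(coded_value="SITTING", decode="Sitting"),
            CodeListItem(coded_value="STANDING", decode="Standing"),
            CodeListItem(coded_value="SUPINE", decode="Supine"),
        ],
    )
    md.code_lists["CL.BODYSITE"] = CodeList(
        oid="CL.BODYSITE",
        name="Measurement site",
        items=[
            CodeListItem(coded_value="LUA", decode="Left upper arm"),
            CodeListItem(coded_value="RUA", decode="Right upper arm"),
        ],
    )
    md.code_lists["CL.ROLE"] = CodeList(
        oid="CL.ROLE",
        name="Performer role",
        items=[
            CodeListItem(coded_value="NURSE", decode="Nurse"),
            CodeListItem(coded_value="PHYSICIAN", decode="Physician"),
        ],
    )
    bp_range = [RangeCheck(comparator="GE", bound=0), RangeCheck(comparator="LE", bound=300)]
    md.item_defs["IT.SYSBP"] = ItemDef(
        oid="IT.SYSBP",
        name="Systolic BP",
        question="Systolic blood pressure",
        datatype="integer",
        measurement_unit="mmHg",
        range_checks=list(bp_range),
    )
    md.item_defs["IT.DIABP"] = ItemDef(
        oid="IT.DIABP",
        name="Diastolic BP",
        question="Diastolic blood pressure",
        datatype="integer",
        measurement_unit="mmHg",
        range_checks=list(bp_range),
    )
    md.item_defs["IT.BPTIME"] = ItemDef(
        oid="IT.BPTIME", name="Measurement time", question="Time of measurement",
        datatype="time",
    )
    md.item_defs["IT.BPPOS"] = ItemDef(
        oid="IT.BPPOS", name="Position", question="Patient position",
        datatype="text", code_list_oid="CL.POSITION",
    )
    md.item_defs["IT.BPSITE"] = ItemDef(
        oid="IT.BPSITE", name="Body site", question="Measurement site",
        datatype="text", code_list_oid="CL.BODYSITE",
    )
    md.item_defs["IT.BPROLE"] = ItemDef(
        oid="IT.BPROLE", name="Performer", question="Measured by",
        datatype="text", code_list_oid="CL.ROLE",
    )
    md.item_group_defs["IG.BP"] = ItemGroupDef(
        oid="IG.BP",
        name="Blood pressure",
        item_refs=["IT.SYSBP", "IT.DIABP", "IT.BPTIME", "IT.BPPOS", "IT.BPSITE", "IT.BPROLE"],
    )
    md.form_defs["F.VITALS"] = FormDef(
        oid="F.VITALS", name="Vital signs", item_group_refs=["IG.BP"]
    )
    md.study_event_defs["SE.BASELINE"] = StudyEventDef(
        oid="SE.BASELINE", name="Baseline visit", event_type="scheduled",
        form_refs=["F.VITALS"],
    )

    study = OdmStudy(
        study_oid="ST.CVS",
        study_name="Cardiovascular episodes study",
        protocol_name="CVS-PROTO-1",
        metadata=md,
        subjects=[
            SubjectData(
                subject_key="SUBJ001",
                events=[
                    StudyEventData(
                        study_event_oid="SE.BASELINE",
                        repeat_key="1",
                        forms=[
                            FormData(
                                form_oid="F.VITALS",
                                item_groups=[
                                    ItemGroupData(
                                        item_group_oid="IG.BP",
                                        items=[
                                            ItemData(item_oid="IT.SYSBP", value="119"),
                                            ItemData(item_oid="IT.DIABP", value="79"),
                                            ItemData(item_oid="IT.BPTIME", value="10:00:00"),
                                            ItemData(item_oid="IT.BPPOS", value="SITTING"),
                                            ItemData(item_oid="IT.BPSITE", value="LUA"),
                                            ItemData(item_oid="IT.BPROLE", value="NURSE"),
                                        ],
                                    )
                                ],
                            )
                        ],
                    )
                ],
            )
        ],
    )

    cfg = MappingConfig(
        observation_groups=["IG.BP"],
        component_parents={"IG.BP": "panel-bp"},
        context_items={
            "bodySite": "IT.BPSITE",
            "position": "IT.BPPOS",
            "performerRole": "IT.BPROLE",
            "effectiveTime": "IT.BPTIME",
        },
        code_map={
            "panel-bp": CodeMapEntry(
                system=LOINC_URI, code="85354-9", display="Blood pressure panel"
            ),
            "IT.SYSBP": CodeMapEntry(
                system=LOINC_URI, code="8480-6", display="Systolic blood pressure"
            ),
            "IT.DIABP": CodeMapEntry(
                system=LOINC_URI, code="8462-4", display="Diastolic blood pressure"
            ),
            "IT.BPPOS": CodeMapEntry(
                system=LOINC_URI, code="8361-8", display="Body position with respect to gravity"
            ),
            "CL.POSITION|SITTING": CodeMapEntry(
                system=SNOMED_URI, code="33586001", display="Sitting position"
            ),
            "CL.BODYSITE|LUA": CodeMapEntry(
                system=SNOMED_URI, code="368208006", display="Left upper arm structure"
            ),
            "CL.ROLE|NURSE": CodeMapEntry(
                system=SNOMED_URI, code="224535009", display="Registered nurse"
            ),
        },
    )
    return study, cfg


def full_coverage_fixture() -> tuple[OdmStudy, MappingConfig]:
    """A compact study exercising every legacy mapping rule.

    Scheduled, unscheduled and repeating events (the repeating one occurs
    twice for the subject); an observation-routed group with a component
    parent; a solo observation-routed item; answer-routed groups holding a
    code-list item, a range-checked float (guaranteeing a
    dropped-constraint ledger entry) and the remaining datatypes.  No
    performer context, so the converted bundle holds exactly the eight
    resource types of the legacy model.
    """
    md = MetaDataVersion(oid="MDV.FC", name="Full coverage metadata")
    md.code_lists["CL.YN"] = CodeList(
        oid="CL.YN",
        name="Yes/No",
        items=[
            CodeListItem(coded_value="Y", decode="Yes"),
            CodeListItem(coded_value="N", decode="No"),
        ],
    )
    md.item_defs["IT.HR"] = ItemDef(
        oid="IT.HR", name="Heart rate", question="Heart rate", datatype="integer",
        measurement_unit="bpm",
        range_checks=[RangeCheck(comparator="GE", bound=0)],
    )
    md.item_defs["IT.TEMP"] = ItemDef(
        oid="IT.TEMP", name="Temperature", question="Body temperature",
        datatype="float", measurement_unit="degC", significant_digits=1,
    )
    md.item_defs["IT.WEIGHT"] = ItemDef(
        oid="IT.WEIGHT", name="Weight", question="Body weight", datatype="float",
        measurement_unit="kg",
        range_checks=[RangeCheck(comparator="GT", bound=0), RangeCheck(comparator="LT", bound=500)],
    )
    md.item_defs["IT.SMOKER"] = ItemDef(
        oid="IT.SMOKER", name="Smoker", question="Current smoker?", datatype="text",
        code_list_oid="CL.YN",
    )
    md.item_defs["IT.NOTE"] = ItemDef(
        oid="IT.NOTE", name="Note", question="Free-text note", datatype="text",
    )
    md.item_defs["IT.PAIN"] = ItemDef(
        oid="IT.PAIN", name="Pain score", question="Pain score (0-10)",
        datatype="integer",
        range_checks=[RangeCheck(comparator="GE", bound=0), RangeCheck(comparator="LE", bound=10)],
    )
    md.item_defs["IT.VISITDATE"] = ItemDef(
        oid="IT.VISITDATE", name="Visit date", question="Date of visit", datatype="date",
    )
    md.item_defs["IT.FASTED"] = ItemDef(
        oid="IT.FASTED", name="Fasted", question="Fasting state?", datatype="boolean",
    )
    md.item_defs["IT.ONSET"] = ItemDef(
        oid="IT.ONSET", name="Onset", question="Symptom onset", datatype="datetime",
    )
    md.item_group_defs["IG.VITALS"] = ItemGroupDef(
        oid="IG.VITALS", name="Vital signs", item_refs=["IT.HR", "IT.TEMP"]
    )
    md.item_group_defs["IG.BODY"] = ItemGroupDef(
        oid="IG.BODY", name="Body measures", item_refs=["IT.WEIGHT"]
    )
    md.item_group_defs["IG.HISTORY"] = ItemGroupDef(
        oid="IG.HISTORY", name="History", item_refs=["IT.SMOKER", "IT.NOTE", "IT.PAIN"]
    )
    md.item_group_defs["IG.VISIT"] = ItemGroupDef(
        oid="IG.VISIT", name="Visit log", item_refs=["IT.VISITDATE", "IT.FASTED", "IT.ONSET"]
    )
    md.form_defs["F.EXAM"] = FormDef(
        oid="F.EXAM", name="Examination", item_group_refs=["IG.VITALS", "IG.HISTORY"]
    )
    md.form_defs["F.BODY"] = FormDef(
        oid="F.BODY", name="Anthropometry", item_group_refs=["IG.BODY"]
    )
    md.form_defs["F.DIARY"] = FormDef(
        oid="F.DIARY", name="Visit diary", item_group_refs=["IG.VISIT"]
    )
    md.study_event_defs["SE.SCREEN"] = StudyEventDef(
        oid="SE.SCREEN", name="Screening", event_type="scheduled",
        form_refs=["F.EXAM", "F.BODY"],
    )
    md.study_event_defs["SE.ADHOC"] = StudyEventDef(
        oid="SE.ADHOC", name="Unscheduled assessment", event_type="unscheduled",
        form_refs=["F.EXAM"],
    )
    md.study_event_defs["SE.DIARY"] = StudyEventDef(
        oid="SE.DIARY", name="Diary", event_type="scheduled", repeating=True,
        form_refs=["F.DIARY"],
    )

    def exam_form(hr: str, temp: str, smoker: str, note: str, pain: str) -> FormData:
        return FormData(
            form_oid="F.EXAM",
            item_groups=[
                ItemGroupData(
                    item_group_oid="IG.VITALS",
                    items=[
                        ItemData(item_oid="IT.HR", value=hr),
                        ItemData(item_oid="IT.TEMP", value=temp),
                    ],
                ),
                ItemGroupData(
                    item_group_oid="IG.HISTORY",
                    items=[
                        ItemData(item_oid="IT.SMOKER", value=smoker),
                        ItemData(item_oid="IT.NOTE", value=note),
                        ItemData(item_oid="IT.PAIN", value=pain),
                    ],
                ),
            ],
        )

    def diary_form(date: str, fasted: str, onset: str) -> FormData:
        return FormData(
            form_oid="F.DIARY",
            item_groups=[
                ItemGroupData(
                    item_group_oid="IG.VISIT",
                    items=[
                        ItemData(item_oid="IT.VISITDATE", value=date),
                        ItemData(item_oid="IT.FASTED", value=fasted),
                        ItemData(item_oid="IT.ONSET", value=onset),
                    ],
                )
            ],
        )

    subjects = [
        SubjectData(
            subject_key="P001",
            events=[
                StudyEventData(
                    study_event_oid="SE.SCREEN",
                    repeat_key="1",
                    forms=[
                        exam_form("72", "36.6", "Y", "baseline exam", "2"),
                        FormData(
                            form_oid="F.BODY",
                            item_groups=[
                                ItemGroupData(
                                    item_group_oid="IG.BODY",
                                    items=[ItemData(item_oid="IT.WEIGHT", value="81.5")],
                                )
                            ],
                        ),
                    ],
                ),
                StudyEventData(
                    study_event_oid="SE.ADHOC",
                    repeat_key="1",
                    forms=[exam_form("88", "37.9", "N", "fever complaint", "6")],
                ),
                StudyEventData(
                    study_event_oid="SE.DIARY",
                    repeat_key="1",
                    forms=[diary_form("2016-03-01", "true", "2016-02-28T22:15:00")],
                ),
                StudyEventData(
                    study_event_oid="SE.DIARY",
                    repeat_key="2",
                    forms=[diary_form("2016-03-08", "false", "2016-03-07T08:30:00")],
                ),
            ],
        ),
        SubjectData(
            subject_key="P002",
            events=[
                StudyEventData(
                    study_event_oid="SE.SCREEN",
                    repeat_key="1",
                    forms=[
                        exam_form("64", "36.4", "N", "unremarkable", "0"),
                        FormData(
                            form_oid="F.BODY",
                            item_groups=[
                                ItemGroupData(
                                    item_group_oid="IG.BODY",
                                    items=[ItemData(item_oid="IT.WEIGHT", value="66.0")],
                                )
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ]

    study = OdmStudy(
        study_oid="ST.FC",
        study_name="Full coverage study",
        protocol_name="FC-PROTO-1",
        metadata=md,
        subjects=subjects,
    )
    cfg = MappingConfig(
        observation_groups=["IG.VITALS", "IG.BODY"],
        component_parents={"IG.VITALS": "panel-vitals"},
        code_map={
            "panel-vitals": CodeMapEntry(
                system="http://example.org/local-codes", code="VITALS", display="Vital signs panel"
            ),
            "IT.HR": CodeMapEntry(system=LOINC_URI, code="8867-4", display="Heart rate"),
            "IT.TEMP": CodeMapEntry(system=LOINC_URI, code="8310-5", display="Body temperature"),
            "IT.WEIGHT": CodeMapEntry(system=LOINC_URI, code="29463-7", display="Body weight"),
        },
    )
    return study, cfg
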