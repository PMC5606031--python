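"""ODM-to-FHIR conversion onto eight legacy resources, with loss accounting.

The converter routes study *metadata* to CarePlan (study definition, one
activity per study event) and Questionnaire (one per form), and *clinical
data* to Patient, ClinicalImpression, EpisodeOfCare, Encounter,
QuestionnaireResponse and Observation.  Routing between the question-answer
style (QuestionnaireResponse) and the observation style (Observation) is a
configuration decision, made per item group with per-item overrides.

Every source datum or constraint the FHIR target cannot carry is recorded
in an append-only :class:`LossLedger`:

* ``dropped-attribute``  — a datum with no FHIR home (e.g. opaque ODM
  extensions, unavailable demographics, invalid leaf values);
* ``dropped-constraint`` — an ODM constraint the target cannot express
  (range checks and significant digits on answer nodes, which have no
  such capability; only Observation can carry a reference range);
* ``retyped``            — a value carried under a different type (coded
  values re-expressed as codeable concepts, time-of-day effective times
  kept as plain times);
* ``repurposed-resource``— a FHIR resource used outside its intended
  purpose (CarePlan and ClinicalImpression foremost, but EpisodeOfCare and
  Encounter are likewise bent to encode the study hierarchy).

The conversion is deterministic: resource ids are slugs of
(resourceType, source OID, subject key, repeat key), so identical inputs
produce byte-identical bundles and ledgers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Literal, Optional

from pydantic import BaseModel, Field

from .errors import MappingConfigError, Violation
from .fhir import CodeableConcept, Coding, FhirBundle, FhirResource, ref
from .odm import (
    CodeList,
    FormData,
    ItemData,
    ItemDef,
    MetaDataVersion,
    OdmStudy,
    StudyEventData,
    SubjectData,
    event_path,
    leaf_path,
    validate_item_value,
)

LossKind = Literal[
    "dropped-attribute", "dropped-constraint", "retyped", "repurposed-resource"
]
LOSS_KINDS = ("dropped-attribute", "dropped-constraint", "retyped", "repurposed-resource")

_FHIR_TYPE_TOKENS = {
    "text": "string",
    "integer": "integer",
    "float": "decimal",
    "date": "date",
    "time": "time",
    "datetime": "dateTime",
    "boolean": "boolean",
}

CONTEXT_ROLES = ("bodySite", "position", "performerRole", "effectiveTime")


def slug(*parts: str | None) -> str:
    """Deterministic FHIR-id-safe slug of the given parts."""
    joined = "-".join(p for p in parts if p)
    cleaned = re.sub(r"[^A-Za-z0-9.-]+", "-", joined).strip("-").lower()
    return cleaned[:64] or "x"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class CodeMapEntry(BaseModel):
    system: str
    code: str
    display: Optional[str] = None

    def concept(self) -> CodeableConcept:
        return CodeableConcept(
            codings=[Coding(system=self.system, code=self.code, display=self.display)],
            text=self.display,
        )


class MappingConfig(BaseModel):
    """Routing rules, terminology bindings, and item designations.

    ``code_map`` keys are either a bare key (an item OID, or an arbitrary
    concept key such as a panel code for multi-component observations) or
    ``"<codeListOid>|<rawValue>"`` for coded values.
    """

    identifier_system: str = "urn:odmfhir:oid"
    observation_groups: list[str] = Field(default_factory=list)
    observation_items: dict[str, bool] = Field(default_factory=dict)
    component_parents: dict[str, str] = Field(default_factory=dict)
    code_map: dict[str, CodeMapEntry] = Field(default_factory=dict)
    demographic_items: dict[str, str] = Field(default_factory=dict)
    context_items: dict[str, str] = Field(default_factory=dict)

    def routed_to_observation(self, item_oid: str, group_oid: str) -> bool:
        if item_oid in self.observation_items:
            return self.observation_items[item_oid]
        return group_oid in self.observation_groups

    def context_role(self, item_oid: str) -> Optional[str]:
        for role, oid in self.context_items.items():
            if oid == item_oid:
                return role
        return None

    # -- YAML wire form (sections: routing / codes / demographics / context)

    @classmethod
    def from_dict(cls, data: dict) -> "MappingConfig":
        routing = data.get("routing") or {}
        return cls(
            identifier_system=data.get("identifier_system", "urn:odmfhir:oid"),
            observation_groups=routing.get("observation_groups") or [],
            observation_items=routing.get("observation_items") or {},
            component_parents=routing.get("component_parents") or {},
            code_map={
                k: CodeMapEntry(**v) for k, v in (data.get("codes") or {}).items()
            },
            demographic_items=data.get("demographics") or {},
            context_items=data.get("context") or {},
        )

    def to_dict(self) -> dict:
        return {
            "identifier_system": self.identifier_system,
            "routing": {
                "observation_groups": list(self.observation_groups),
                "observation_items": dict(self.observation_items),
                "component_parents": dict(self.component_parents),
            },
            "codes": {
                k: {kk: vv for kk, vv in v.model_dump().items() if vv is not None}
                for k, v in self.code_map.items()
            },
            "demographics": dict(self.demographic_items),
            "context": dict(self.context_items),
        }


def validate_config(cfg: MappingConfig, study: OdmStudy) -> None:
    """Hard-fail (before any output) if the config names unknown OIDs."""
    md = study.metadata
    problems: list[str] = []
    for oid in cfg.observation_groups:
        if oid not in md.item_group_defs:
            problems.append(f"observation group {oid!r} not in metadata")
    for oid in cfg.observation_items:
        if oid not in md.item_defs:
            problems.append(f"observation item {oid!r} not in metadata")
    for oid in cfg.component_parents:
        if oid not in md.item_group_defs:
            problems.append(f"component-parent group {oid!r} not in metadata")
    for role, oid in cfg.demographic_items.items():
        if role not in ("gender", "birthDate"):
            problems.append(f"unknown demographic designation {role!r}")
        elif oid not in md.item_defs:
            problems.append(f"demographic item {oid!r} not in metadata")
    for role, oid in cfg.context_items.items():
        if role not in CONTEXT_ROLES:
            problems.append(f"unknown context designation {role!r}")
        elif oid not in md.item_defs:
            problems.append(f"context item {oid!r} not in metadata")
    if problems:
        raise MappingConfigError("; ".join(problems))


# ---------------------------------------------------------------------------
# Loss ledger
# ---------------------------------------------------------------------------


class LossEntry(BaseModel):
    source_path: str
    kind: LossKind
    note: str


class LossLedger(BaseModel):
    """Ordered, append-only record of information the target could not carry."""

    entries: list[LossEntry] = Field(default_factory=list)

    def add(self, source_path: str, kind: LossKind, note: str) -> None:
        self.entries.append(LossEntry(source_path=source_path, kind=kind, note=note))

    def by_kind(self, kind: LossKind) -> list[LossEntry]:
        return [e for e in self.entries if e.kind == kind]

    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in LOSS_KINDS}
        for e in self.entries:
            out[e.kind] += 1
        return out


def loss_report(ledger: LossLedger, format: str = "text") -> str:
    """Render the ledger, grouped by kind with per-kind counts.

    ``format="json"`` gives the machine-readable form; ``"text"`` a
    human-readable table.  Ordering is stable (ledger order within kinds).
    """
    counts = ledger.counts()
    if format == "json":
        doc = {
            "counts": counts,
            "total": len(ledger.entries),
            "entries": [
                {"sourcePath": e.source_path, "kind": e.kind, "note": e.note}
                for e in ledger.entries
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    lines = ["Loss report", "==========="]
    for kind in LOSS_KINDS:
        lines.append(f"{kind}: {counts[kind]}")
    lines.append(f"total: {len(ledger.entries)}")
    for kind in LOSS_KINDS:
        entries = ledger.by_kind(kind)
        if not entries:
            continue
        lines.append("")
        lines.append(f"[{kind}]")
        for e in entries:
            lines.append(f"  {e.source_path}: {e.note}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Terminology binding and datatype conversion
# ---------------------------------------------------------------------------


def bind_code(key: str, raw: Optional[str], code_map: dict[str, CodeMapEntry]) -> CodeableConcept:
    """Look up a concept for ``key`` (optionally specialized by raw value).

    Lookup order: ``"key|raw"`` then ``key``; falls back to a text-only
    concept (the sanctioned empty-codings fallback) and never fails.
    """
    if raw is not None and f"{key}|{raw}" in code_map:
        return code_map[f"{key}|{raw}"].concept()
    if key in code_map:
        return code_map[key].concept()
    return CodeableConcept(text=raw if raw is not None else key)


def item_concept(item_def: ItemDef, cfg: MappingConfig) -> CodeableConcept:
    """Concept identifying an item: mapped code, else its question text."""
    if item_def.oid in cfg.code_map:
        return cfg.code_map[item_def.oid].concept()
    return CodeableConcept(text=item_def.question or item_def.name or item_def.oid)


def value_concept(
    item_def: ItemDef,
    raw: str,
    code_lists: dict[str, CodeList],
    cfg: MappingConfig,
) -> CodeableConcept:
    """Concept for a coded value: mapped code, else the code list decode."""
    if item_def.code_list_oid is not None:
        key = f"{item_def.code_list_oid}|{raw}"
        if key in cfg.code_map:
            return cfg.code_map[key].concept()
        cl = code_lists.get(item_def.code_list_oid)
        decode = cl.decode(raw) if cl is not None else None
        return CodeableConcept(text=decode or raw)
    return bind_code(item_def.oid, raw, cfg.code_map)


def convert_datatype(
    item_def: ItemDef,
    typed,
    *,
    target: str,
    source_path: str = "",
    ledger: Optional[LossLedger] = None,
    code_lists: Optional[dict[str, CodeList]] = None,
    cfg: Optional[MappingConfig] = None,
    raw: Optional[str] = None,
) -> tuple[str, object]:
    """Convert a validated ODM value to a FHIR typed value.

    Returns ``(value_key, json_value)`` — e.g. ``("valueInteger", 119)``.
    Constraints the *target* form cannot carry are recorded to the ledger:
    answer nodes can express neither range checks nor significant digits
    nor declared lengths; Observation carries range checks as reference
    ranges but still drops significant digits and lengths.
    """

    def note(kind: str, text: str) -> None:
        if ledger is not None:
            ledger.add(source_path, kind, text)

    if target == "answer":
        for rc in item_def.range_checks:
            note(
                "dropped-constraint",
                f"range check {rc.comparator} {rc.bound} on {item_def.oid} "
                "not representable in a question answer",
            )
    if item_def.significant_digits is not None:
        note(
            "dropped-constraint",
            f"significantDigits={item_def.significant_digits} on {item_def.oid} "
            f"not representable in {target}",
        )
    if item_def.length is not None:
        note(
            "dropped-constraint",
            f"length={item_def.length} on {item_def.oid} not representable in {target}",
        )

    if item_def.code_list_oid is not None:
        concept = value_concept(
            item_def, raw if raw is not None else str(typed), code_lists or {}, cfg or MappingConfig()
        )
        note("retyped", f"coded value on {item_def.oid} re-expressed as CodeableConcept")
        return "valueCodeableConcept", concept.to_json()

    dt = item_def.datatype
    if dt == "integer":
        return "valueInteger", int(typed)
    if dt == "float":
        return "valueDecimal", float(typed)
    if dt == "boolean":
        return "valueBoolean", bool(typed)
    if dt in ("date", "time", "datetime"):
        key = {"date": "valueDate", "time": "valueTime", "datetime": "valueDateTime"}[dt]
        return key, typed.isoformat()
    return "valueString", str(typed)


def _reference_ranges(
    item_def: ItemDef, source_path: str, ledger: LossLedger
) -> list[dict]:
    """Range checks as Observation reference ranges (inclusive/exclusive
    bounds kept via the comparator); EQ/NE have no range form and are
    recorded as dropped constraints."""
    out: list[dict] = []
    for rc in item_def.range_checks:
        entry: dict = {"comparator": rc.comparator}
        bound = {"value": float(rc.bound)}
        if item_def.measurement_unit:
            bound["unit"] = item_def.measurement_unit
        if rc.comparator in ("GE", "GT"):
            entry["low"] = bound
        elif rc.comparator in ("LE", "LT"):
            entry["high"] = bound
        else:
            ledger.add(
                source_path,
                "dropped-constraint",
                f"range check {rc.comparator} {rc.bound} on {item_def.oid} "
                "has no referenceRange form",
            )
            continue
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# Per-entity mapping operations
# ---------------------------------------------------------------------------


def map_form_def(
    form_def, metadata: MetaDataVersion, cfg: Optional[MappingConfig] = None
) -> FhirResource:
    """One Questionnaire per form: group tree mirrors the item groups, one
    question node per item (code-list options included)."""
    cfg = cfg or MappingConfig()
    groups = []
    for goid in form_def.item_group_refs:
        igd = metadata.item_group_defs[goid]
        questions = []
        for ioid in igd.item_refs:
            idf = metadata.item_defs[ioid]
            q: dict = {
                "linkId": idf.oid,
                "text": idf.question or idf.name,
                "type": "choice" if idf.code_list_oid else _FHIR_TYPE_TOKENS[idf.datatype],
            }
            if idf.code_list_oid and idf.code_list_oid in metadata.code_lists:
                cl = metadata.code_lists[idf.code_list_oid]
                q["option"] = [
                    {"code": ci.coded_value, **({"display": ci.decode} if ci.decode else {})}
                    for ci in cl.items
                ]
            questions.append(q)
        groups.append({"linkId": igd.oid, "title": igd.name, "question": questions})
    return FhirResource(
        resource_type="Questionnaire",
        id=f"questionnaire-{slug(form_def.oid)}",
        identifier=[{"system": cfg.identifier_system, "value": form_def.oid}],
        attrs={
            "status": "published",
            "version": "1",
            "publisher": "odmfhir",
            "group": {"linkId": form_def.oid, "title": form_def.name, "group": groups},
        },
    )


def map_study_def(study: OdmStudy, cfg: Optional[MappingConfig] = None) -> FhirResource:
    """The study definition as a CarePlan: protocol in ``support``,
    coordinator in ``participant``, one activity per study event whose
    ``detail.scheduled`` carries the scheduled/unscheduled marker and whose
    ``actionResulting`` references the event's Questionnaires.

    The study title has no designated CarePlan attribute; it is carried in
    ``description`` plus an identifier (an inferred mapping).
    """
    cfg = cfg or MappingConfig()
    activities = []
    for sed in study.metadata.study_event_defs.values():
        activities.append(
            {
                "detail": {"scheduled": sed.event_type},
                "actionResulting": [
                    ref("Questionnaire", f"questionnaire-{slug(foid)}")
                    for foid in sed.form_refs
                ],
            }
        )
    attrs: dict = {
        "status": "active",
        "description": study.study_name,
        "category": [{"text": "clinical study"}],
        "participant": [{"role": {"text": "study coordinator"}}],
        "activity": activities,
    }
    if study.protocol_name:
        attrs["support"] = [{"display": study.protocol_name}]
    return FhirResource(
        resource_type="CarePlan",
        id=f"careplan-{slug(study.study_oid)}",
        identifier=[{"system": cfg.identifier_system, "value": study.study_oid}],
        attrs=attrs,
    )


def build_patient(
    subj: SubjectData,
    study: OdmStudy,
    cfg: MappingConfig,
    ledger: LossLedger,
) -> FhirResource:
    """Patient for one subject; gender/birthDate pulled from the designated
    demographic items when present (ODM itself records no demographics)."""
    attrs: dict = {}
    found_any = False
    gender_oid = cfg.demographic_items.get("gender")
    birth_oid = cfg.demographic_items.get("birthDate")
    for path, _subj, _evt, _form, _grp, item in study_leaves_of(subj):
        if gender_oid and item.item_oid == gender_oid:
            found_any = True
            idf = study.metadata.item_defs.get(item.item_oid)
            decode = None
            if idf is not None and idf.code_list_oid:
                cl = study.metadata.code_lists.get(idf.code_list_oid)
                decode = cl.decode(item.value) if cl else None
            attrs["gender"] = (decode or item.value).lower()
        elif birth_oid and item.item_oid == birth_oid:
            found_any = True
            import datetime as _dt

            try:
                _dt.date.fromisoformat(item.value.strip())
            except ValueError:
                ledger.add(
                    path,
                    "dropped-attribute",
                    f"birthDate value {item.value!r} unparseable as date; field left empty",
                )
            else:
                attrs["birthDate"] = item.value.strip()
    if not found_any:
        ledger.add(
            f"subject[{subj.subject_key}]",
            "dropped-attribute",
            "demographics unavailable: no designated demographic items in subject data",
        )
    return FhirResource(
        resource_type="Patient",
        id=f"patient-{slug(subj.subject_key)}",
        identifier=[{"system": cfg.identifier_system, "value": subj.subject_key}],
        attrs=attrs,
    )


def study_leaves_of(subj: SubjectData):
    for evt in subj.events:
        for form in evt.forms:
            for grp in form.item_groups:
                for item in grp.items:
                    yield leaf_path(subj.subject_key, evt, form, grp, item), subj, evt, form, grp, item


def map_subject(
    subj: SubjectData,
    study: OdmStudy,
    cfg: MappingConfig,
    ledger: LossLedger,
    plan_id: Optional[str] = None,
) -> tuple[FhirResource, FhirResource]:
    """Patient + ClinicalImpression for one subject.  The impression links
    the patient and the study CarePlan; it is repurposed (it cannot model
    the study hierarchy) and the ledger says so."""
    patient = build_patient(subj, study, cfg, ledger)
    plan_id = plan_id or f"careplan-{slug(study.study_oid)}"
    impression = FhirResource(
        resource_type="ClinicalImpression",
        id=f"impression-{slug(subj.subject_key)}",
        attrs={
            "status": "completed",
            "patient": ref(patient),
            "plan": [ref("CarePlan", plan_id)],
            "summary": f"Clinical study data for subject {subj.subject_key}",
        },
    )
    ledger.add(
        f"subject[{subj.subject_key}]",
        "repurposed-resource",
        "ClinicalImpression holds converted study data; it cannot model the "
        "study hierarchy and is not used as intended",
    )
    return patient, impression


def map_event_data(
    evt: StudyEventData,
    subject_key: str,
    ledger: Optional[LossLedger] = None,
) -> tuple[FhirResource, FhirResource]:
    """EpisodeOfCare per (subject, event, repeat) and one Encounter per
    constituent visit.  ODM has no visit element, so the repeat occurrence
    is the only observable visit proxy: one Encounter per repeat."""
    rk = evt.repeat_key or "1"
    patient_ref = ref("Patient", f"patient-{slug(subject_key)}")
    episode = FhirResource(
        resource_type="EpisodeOfCare",
        id=f"episode-{slug(subject_key, evt.study_event_oid, rk)}",
        attrs={"status": "finished", "patient": patient_ref},
    )
    encounter = FhirResource(
        resource_type="Encounter",
        id=f"encounter-{slug(subject_key, evt.study_event_oid, rk)}",
        attrs={"status": "finished", "episodeOfCare": ref(episode), "patient": patient_ref},
    )
    if ledger is not None:
        epath = event_path(subject_key, evt)
        ledger.add(
            epath,
            "repurposed-resource",
            "EpisodeOfCare encodes a study event, not an episode of care as intended",
        )
        ledger.add(
            epath,
            "repurposed-resource",
            "Encounter encodes a study-event visit inferred from the repeat key",
        )
    return episode, encounter


# ---------------------------------------------------------------------------
# Form processing (shared by the legacy converter and the native builder)
# ---------------------------------------------------------------------------


@dataclass
class FormOutput:
    answer_groups: list[dict] = field(default_factory=list)
    observations: list[FhirResource] = field(default_factory=list)


def process_form(
    form_data: FormData,
    evt: StudyEventData,
    subj: SubjectData,
    study: OdmStudy,
    cfg: MappingConfig,
    ledger: LossLedger,
    dispositions: dict[str, str],
    practitioners: dict[str, FhirResource],
    *,
    subject_ref: dict,
    encounter_ref: Optional[dict] = None,
) -> FormOutput:
    """Convert one FormData: answer-routed leaves become question-answer
    nodes, observation-routed groups become Observations (one multi-
    component Observation when the group has a configured parent code).

    Every leaf ends in exactly one place or gets a ledger entry; the
    disposition map records where (answer / observation-value /
    observation-component / observation-context / dropped).
    """
    md = study.metadata
    rk = evt.repeat_key or "1"
    out = FormOutput()

    for grp in form_data.item_groups:
        answer_items: list[tuple[str, ItemDef, ItemData, object]] = []
        obs_items: list[tuple[str, ItemDef, ItemData, object]] = []
        for item in grp.items:
            path = leaf_path(subj.subject_key, evt, form_data, grp, item)
            idf = md.item_defs[item.item_oid]
            check = validate_item_value(idf, item.value, md.code_lists)
            if check.value is None and check.violations:
                ledger.add(
                    path,
                    "dropped-attribute",
                    f"value {item.value!r} invalid for {idf.oid}: "
                    f"{check.violations[0].message}; leaf not converted",
                )
                dispositions[path] = "dropped"
                continue
            if cfg.routed_to_observation(item.item_oid, grp.item_group_oid):
                obs_items.append((path, idf, item, check.value))
            else:
                answer_items.append((path, idf, item, check.value))

        if answer_items:
            questions = []
            for path, idf, item, typed in answer_items:
                key, value = convert_datatype(
                    idf,
                    typed,
                    target="answer",
                    source_path=path,
                    ledger=ledger,
                    code_lists=md.code_lists,
                    cfg=cfg,
                    raw=item.value,
                )
                questions.append(
                    {
                        "linkId": idf.oid,
                        "text": idf.question or idf.name,
                        "answer": [{key: value}],
                    }
                )
                dispositions[path] = "answer"
            out.answer_groups.append(
                {"linkId": grp.item_group_oid, "question": questions}
            )

        if not obs_items:
            continue

        parent_key = cfg.component_parents.get(grp.item_group_oid)
        if parent_key is not None:
            obs = _component_observation(
                parent_key,
                grp.item_group_oid,
                obs_items,
                study,
                cfg,
                ledger,
                dispositions,
                practitioners,
                obs_id=f"obs-{slug(subj.subject_key, evt.study_event_oid, rk, grp.item_group_oid)}",
                subject_ref=subject_ref,
                encounter_ref=encounter_ref,
            )
            out.observations.append(obs)
        else:
            for path, idf, item, typed in obs_items:
                obs = _solo_observation(
                    path,
                    idf,
                    item,
                    typed,
                    study,
                    cfg,
                    ledger,
                    obs_id=f"obs-{slug(subj.subject_key, evt.study_event_oid, rk, idf.oid)}",
                    subject_ref=subject_ref,
                    encounter_ref=encounter_ref,
                )
                dispositions[path] = "observation-value"
                out.observations.append(obs)
    return out


def _practitioner_for_role(
    role_def: ItemDef,
    raw: str,
    study: OdmStudy,
    cfg: MappingConfig,
    practitioners: dict[str, FhirResource],
) -> FhirResource:
    concept = value_concept(role_def, raw, study.metadata.code_lists, cfg)
    display = concept.text or (concept.codings[0].display if concept.codings else raw)
    pid = f"practitioner-{slug(display or raw)}"
    if pid not in practitioners:
        practitioners[pid] = FhirResource(
            resource_type="Practitioner",
            id=pid,
            attrs={"name": display or raw, "role": concept.to_json()},
        )
    return practitioners[pid]


def _component_observation(
    parent_key: str,
    group_oid: str,
    obs_items,
    study: OdmStudy,
    cfg: MappingConfig,
    ledger: LossLedger,
    dispositions: dict[str, str],
    practitioners: dict[str, FhirResource],
    *,
    obs_id: str,
    subject_ref: dict,
    encounter_ref: Optional[dict],
) -> FhirResource:
    """One Observation for the whole group: measurement items become
    components under the configured parent code; designated context items
    attach as bodySite / position component / performer / effective time."""
    md = study.metadata
    attrs: dict = {
        "status": "final",
        "code": bind_code(parent_key, None, cfg.code_map).to_json(),
        "subject": subject_ref,
    }
    if encounter_ref is not None:
        attrs["encounter"] = encounter_ref
    components: list[dict] = []

    for path, idf, item, typed in obs_items:
        role = cfg.context_role(idf.oid)
        if role == "bodySite":
            attrs["bodySite"] = value_concept(idf, item.value, md.code_lists, cfg).to_json()
            dispositions[path] = "observation-context"
        elif role == "position":
            components.append(
                {
                    "code": item_concept(idf, cfg).to_json(),
                    "valueCodeableConcept": value_concept(
                        idf, item.value, md.code_lists, cfg
                    ).to_json(),
                }
            )
            dispositions[path] = "observation-component"
        elif role == "performerRole":
            practitioner = _practitioner_for_role(idf, item.value, study, cfg, practitioners)
            attrs["performer"] = [ref(practitioner)]
            dispositions[path] = "observation-context"
        elif role == "effectiveTime":
            if idf.datatype == "datetime":
                attrs["effectiveDateTime"] = typed.isoformat()
            else:
                attrs["effectiveTime"] = (
                    typed.isoformat() if hasattr(typed, "isoformat") else str(typed)
                )
                ledger.add(
                    path,
                    "retyped",
                    "time-of-day effective time kept as a plain time, not promoted "
                    "to a full timestamp",
                )
            dispositions[path] = "observation-context"
        else:
            comp: dict = {"code": item_concept(idf, cfg).to_json()}
            if idf.datatype in ("integer", "float") and idf.measurement_unit:
                comp["valueQuantity"] = {
                    "value": int(typed) if idf.datatype == "integer" else float(typed),
                    "unit": idf.measurement_unit,
                }
                if idf.significant_digits is not None or idf.length is not None:
                    convert_datatype(
                        idf, typed, target="observation", source_path=path,
                        ledger=ledger, code_lists=md.code_lists, cfg=cfg, raw=item.value,
                    )
            else:
                key, value = convert_datatype(
                    idf, typed, target="observation", source_path=path,
                    ledger=ledger, code_lists=md.code_lists, cfg=cfg, raw=item.value,
                )
                comp[key] = value
            ranges = _reference_ranges(idf, path, ledger)
            if ranges:
                comp["referenceRange"] = ranges
            components.append(comp)
            dispositions[path] = "observation-component"
    if components:
        attrs["component"] = components
    return FhirResource(resource_type="Observation", id=obs_id, attrs=attrs)


def _solo_observation(
    path: str,
    idf: ItemDef,
    item: ItemData,
    typed,
    study: OdmStudy,
    cfg: MappingConfig,
    ledger: LossLedger,
    *,
    obs_id: str,
    subject_ref: dict,
    encounter_ref: Optional[dict],
) -> FhirResource:
    md = study.metadata
    attrs: dict = {
        "status": "final",
        "code": item_concept(idf, cfg).to_json(),
        "subject": subject_ref,
    }
    if encounter_ref is not None:
        attrs["encounter"] = encounter_ref
    if idf.datatype in ("integer", "float") and idf.measurement_unit:
        attrs["valueQuantity"] = {
            "value": int(typed) if idf.datatype == "integer" else float(typed),
            "unit": idf.measurement_unit,
        }
        if idf.significant_digits is not None or idf.length is not None:
            convert_datatype(
                idf, typed, target="observation", source_path=path,
                ledger=ledger, code_lists=md.code_lists, cfg=cfg, raw=item.value,
            )
    else:
        key, value = convert_datatype(
            idf, typed, target="observation", source_path=path,
            ledger=ledger, code_lists=md.code_lists, cfg=cfg, raw=item.value,
        )
        attrs[key] = value
    ranges = _reference_ranges(idf, path, ledger)
    if ranges:
        attrs["referenceRange"] = ranges
    return FhirResource(resource_type="Observation", id=obs_id, attrs=attrs)


def map_item_data(
    item: ItemData,
    item_def: ItemDef,
    cfg: MappingConfig,
    *,
    study: OdmStudy,
    group_oid: str,
    source_path: str = "",
    ledger: Optional[LossLedger] = None,
    subject_ref: Optional[dict] = None,
    encounter_ref: Optional[dict] = None,
    obs_id: str = "obs-x",
):
    """Route one leaf: ``("answer", question_node)`` for question-answer
    items, ``("observation", resource)`` for observation-routed ones."""
    ledger = ledger if ledger is not None else LossLedger()
    check = validate_item_value(item_def, item.value, study.metadata.code_lists)
    if cfg.routed_to_observation(item_def.oid, group_oid):
        obs = _solo_observation(
            source_path,
            item_def,
            item,
            check.value,
            study,
            cfg,
            ledger,
            obs_id=obs_id,
            subject_ref=subject_ref or {"display": "subject"},
            encounter_ref=encounter_ref,
        )
        return "observation", obs
    key, value = convert_datatype(
        item_def,
        check.value,
        target="answer",
        source_path=source_path,
        ledger=ledger,
        code_lists=study.metadata.code_lists,
        cfg=cfg,
        raw=item.value,
    )
    node = {
        "linkId": item_def.oid,
        "text": item_def.question or item_def.name,
        "answer": [{key: value}],
    }
    return "answer", node


# ---------------------------------------------------------------------------
# Whole-study conversion
# ---------------------------------------------------------------------------


@dataclass
class MappingResult:
    """Bundle + ledger, plus the per-leaf disposition map used for
    conservation accounting.  Unpacks as ``bundle, ledger = result``."""

    bundle: FhirBundle
    ledger: LossLedger
    dispositions: dict[str, str]

    def __iter__(self):
        return iter((self.bundle, self.ledger))


def _extras_to_ledger(study: OdmStudy, ledger: LossLedger) -> None:
    for snippet in study.extras:
        ledger.add("document", "dropped-attribute", f"opaque ODM extension not mapped: {snippet[:120]}")
    for snippet in study.metadata.extras:
        ledger.add("metadata", "dropped-attribute", f"opaque ODM extension not mapped: {snippet[:120]}")
    for idf in study.metadata.item_defs.values():
        for snippet in idf.extras:
            ledger.add(
                f"metadata/itemDef[{idf.oid}]",
                "dropped-attribute",
                f"opaque ODM extension not mapped: {snippet[:120]}",
            )
    for subj in study.subjects:
        for snippet in subj.extras:
            ledger.add(
                f"subject[{subj.subject_key}]",
                "dropped-attribute",
                f"opaque ODM extension not mapped: {snippet[:120]}",
            )


def map_study(study: OdmStudy, cfg: MappingConfig) -> MappingResult:
    """Convert a whole study to the eight-resource legacy bundle.

    The bundle always contains the metadata resources (CarePlan and one
    Questionnaire per form); subjects contribute Patient and
    ClinicalImpression, study-event occurrences contribute EpisodeOfCare
    and Encounter, and leaves land in QuestionnaireResponses or
    Observations per the routing config.  Config OIDs that do not resolve
    are a hard error before any output.
    """
    validate_config(cfg, study)
    ledger = LossLedger()
    dispositions: dict[str, str] = {}
    bundle = FhirBundle()
    practitioners: dict[str, FhirResource] = {}

    careplan = map_study_def(study, cfg)
    bundle.add(careplan)
    ledger.add(
        f"study[{study.study_oid}]",
        "repurposed-resource",
        "CarePlan models the study definition rather than an individual's "
        "care plan (not used as intended); study title carried in description "
        "(inferred mapping)",
    )
    for fd in study.metadata.form_defs.values():
        bundle.add(map_form_def(fd, study.metadata, cfg))

    _extras_to_ledger(study, ledger)

    for subj in study.subjects:
        patient, impression = map_subject(subj, study, cfg, ledger, careplan.id)
        bundle.add(patient)
        subject_ref = ref(patient)
        investigation_refs: list[dict] = []
        for evt in subj.events:
            episode, encounter = map_event_data(evt, subj.subject_key, ledger)
            bundle.add(episode)
            bundle.add(encounter)
            encounter_ref = ref(encounter)
            rk = evt.repeat_key or "1"
            for form_data in evt.forms:
                fo = process_form(
                    form_data,
                    evt,
                    subj,
                    study,
                    cfg,
                    ledger,
                    dispositions,
                    practitioners,
                    subject_ref=subject_ref,
                    encounter_ref=encounter_ref,
                )
                if fo.answer_groups:
                    qr = FhirResource(
                        resource_type="QuestionnaireResponse",
                        id=f"response-{slug(subj.subject_key, evt.study_event_oid, rk, form_data.form_oid)}",
                        attrs={
                            "status": "completed",
                            "questionnaire": ref(
                                "Questionnaire", f"questionnaire-{slug(form_data.form_oid)}"
                            ),
                            "subject": subject_ref,
                            "encounter": encounter_ref,
                            "group": {
                                "linkId": form_data.form_oid,
                                "group": fo.answer_groups,
                            },
                        },
                    )
                    bundle.add(qr)
                    investigation_refs.append(ref(qr))
                for obs in fo.observations:
                    bundle.add(obs)
                    investigation_refs.append(ref(obs))
        if investigation_refs:
            impression.attrs["investigations"] = [
                {"code": {"text": "study data"}, "item": investigation_refs}
            ]
        bundle.add(impression)

    for pid in sorted(practitioners):
        bundle.add(practitioners[pid])
    return MappingResult(bundle=bundle, ledger=ledger, dispositions=dispositions)


def count_leaves(study: OdmStudy) -> int:
    return sum(1 for _ in study.iter_leaves())


def conservation_counts(study: OdmStudy, result: MappingResult) -> dict[str, int]:
    """Leaf-conservation bookkeeping: every ItemData leaf must be an answer,
    an observation contribution (value, component, or context attachment),
    or a dropped-leaf ledger entry."""
    leaf_paths = {path for path, *_ in study.iter_leaves()}
    answers = sum(1 for d in result.dispositions.values() if d == "answer")
    observation = sum(
        1
        for d in result.dispositions.values()
        if d in ("observation-value", "observation-component", "observation-context")
    )
    dropped = sum(
        1
        for e in result.ledger.entries
        if e.kind == "dropped-attribute" and e.source_path in leaf_paths
        and result.dispositions.get(e.source_path) == "dropped"
    )
    return {
        "leaves": len(leaf_paths),
        "answers": answers,
        "observation": observation,
        "dropped": dropped,
    }
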