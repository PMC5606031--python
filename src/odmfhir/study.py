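"""Native FHIR resources for clinical studies: ClinicalStudyPlan and
ClinicalStudyData.

These two resources describe a research study directly in FHIR, instead of
bending care-delivery resources around the study hierarchy.  The plan holds
the protocol/registration metadata (title, sponsor, registration date,
sample size, goals) and the planned activities; the data resource holds one
patient's captured data organised as events and visits, where each visit's
``investigations`` is a choice of exactly one of: a single
QuestionnaireResponse reference, one or more Observation references, or one
or more ImagingManifest references.

Because ODM carries none of the registration metadata, the plan builder
takes a separate protocol-metadata mapping (typically a YAML file) for
those fields.  The data builder reuses the converter's form processing, so
clinical values land in first-class Observations/QuestionnaireResponses —
the native path repurposes no resource, which is the point.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field

from .errors import InvestigationMixError, ProtocolMetaError, Violation
from .fhir import FhirBundle, FhirResource, ref
from .mapping import (
    LossLedger,
    MappingConfig,
    bind_code,
    build_patient,
    map_form_def,
    process_form,
    slug,
    validate_config,
)
from .odm import OdmStudy, StudyEventData, SubjectData, event_path

EVENT_STATUSES = ("planned", "in-progress", "finished", "cancelled")
VISIT_SCHEDULED = ("planned", "unplanned")


# ---------------------------------------------------------------------------
# ClinicalStudyPlan
# ---------------------------------------------------------------------------


class ContactDetail(BaseModel):
    name: Optional[str] = None
    telecom: list[str] = Field(default_factory=list)


class Goal(BaseModel):
    """A study outcome with its measurement metric and timepoint(s)."""

    outcome: Optional[str] = None
    metric: Optional[str] = None
    timepoint: Optional[str] = None


class ActivityDetail(BaseModel):
    category: Optional[dict] = None
    type: Optional[dict] = None
    rationale: Optional[str] = None


class PlanActivity(BaseModel):
    scheduled: Optional[str] = None
    action_resulting: list[dict] = Field(default_factory=list)
    detail: list[ActivityDetail] = Field(default_factory=list)
    performer: Optional[dict] = None
    location: Optional[dict] = None


class ClinicalStudyPlan(BaseModel):
    """Protocol/registration metadata plus the planned activities.

    All fields are optional at the model level so that partially built
    plans can be validated; :func:`validate_plan` enforces the invariants
    (mandatory status, three-part goals, positive sample size, activities
    carrying detail items or a Questionnaire reference).
    """

    identifier: Optional[str] = None
    external_identifier: Optional[str] = None
    title: Optional[str] = None
    official_title: Optional[str] = None
    registration_date: Optional[str] = None
    authoring_body: Optional[str] = None
    status: Optional[str] = None
    sponsor: list[dict] = Field(default_factory=list)
    public_contact: Optional[ContactDetail] = None
    investigator: Optional[dict] = None
    description: Optional[str] = None
    date_first_enrolment: Optional[str] = None
    sample_size: Optional[int] = None
    goal: list[Goal] = Field(default_factory=list)
    activity: list[PlanActivity] = Field(default_factory=list)
    note: Optional[str] = None

    @property
    def resource_id(self) -> str:
        return f"plan-{slug(self.identifier or 'study')}"

    def to_resource(self) -> FhirResource:
        attrs: dict = {}
        simple = {
            "title": self.title,
            "officialTitle": self.official_title,
            "registrationDate": self.registration_date,
            "authoringBody": self.authoring_body,
            "status": self.status,
            "description": self.description,
            "dateFirstEnrolment": self.date_first_enrolment,
            "sampleSize": self.sample_size,
            "note": self.note,
            "externalIdentifier": self.external_identifier,
        }
        for key, value in simple.items():
            if value is not None:
                attrs[key] = value
        if self.sponsor:
            attrs["sponsor"] = self.sponsor
        if self.public_contact is not None:
            attrs["publicContact"] = {
                k: v
                for k, v in (
                    ("name", self.public_contact.name),
                    ("telecom", self.public_contact.telecom or None),
                )
                if v is not None
            }
        if self.investigator is not None:
            attrs["investigator"] = self.investigator
        if self.goal:
            attrs["goal"] = [
                {k: v for k, v in g.model_dump().items() if v is not None}
                for g in self.goal
            ]
        if self.activity:
            acts = []
            for a in self.activity:
                entry: dict = {}
                if a.scheduled is not None:
                    entry["scheduled"] = a.scheduled
                if a.action_resulting:
                    entry["actionResulting"] = a.action_resulting
                if a.detail:
                    entry["detail"] = [
                        {k: v for k, v in d.model_dump().items() if v is not None}
                        for d in a.detail
                    ]
                if a.performer is not None:
                    entry["performer"] = a.performer
                if a.location is not None:
                    entry["location"] = a.location
                acts.append(entry)
            attrs["activity"] = acts
        identifier = (
            [{"system": "urn:odmfhir:study", "value": self.identifier}]
            if self.identifier
            else []
        )
        return FhirResource(
            resource_type="ClinicalStudyPlan",
            id=self.resource_id,
            identifier=identifier,
            attrs=attrs,
        )

    @classmethod
    def from_resource(cls, r: FhirResource) -> "ClinicalStudyPlan":
        a = r.attrs
        contact = a.get("publicContact")
        return cls(
            identifier=(r.identifier[0]["value"] if r.identifier else None),
            external_identifier=a.get("externalIdentifier"),
            title=a.get("title"),
            official_title=a.get("officialTitle"),
            registration_date=a.get("registrationDate"),
            authoring_body=a.get("authoringBody"),
            status=a.get("status"),
            sponsor=a.get("sponsor") or [],
            public_contact=(
                ContactDetail(name=contact.get("name"), telecom=contact.get("telecom") or [])
                if contact
                else None
            ),
            investigator=a.get("investigator"),
            description=a.get("description"),
            date_first_enrolment=a.get("dateFirstEnrolment"),
            sample_size=a.get("sampleSize"),
            goal=[Goal(**g) for g in a.get("goal") or []],
            activity=[
                PlanActivity(
                    scheduled=entry.get("scheduled"),
                    action_resulting=entry.get("actionResulting") or [],
                    detail=[ActivityDetail(**d) for d in entry.get("detail") or []],
                    performer=entry.get("performer"),
                    location=entry.get("location"),
                )
                for entry in a.get("activity") or []
            ],
            note=a.get("note"),
        )


def validate_plan(plan: ClinicalStudyPlan) -> list[Violation]:
    """Invariants: mandatory status; each goal has exactly its three
    sub-fields; sampleSize positive; each activity carries detailed items
    or a Questionnaire reference."""
    out: list[Violation] = []
    if not plan.status:
        out.append(Violation("status", "mandatory status attribute is missing"))
    for i, g in enumerate(plan.goal):
        for part in ("outcome", "metric", "timepoint"):
            if not getattr(g, part):
                out.append(Violation(f"goal[{i}].{part}", "goal sub-attribute missing"))
    if plan.sample_size is not None and plan.sample_size <= 0:
        out.append(Violation("sampleSize", f"sampleSize must be positive, got {plan.sample_size}"))
    for i, a in enumerate(plan.activity):
        if not a.detail and not a.action_resulting:
            out.append(
                Violation(
                    f"activity[{i}]",
                    "activity needs detailed items or a Questionnaire reference",
                )
            )
    return out


def build_plan(
    study: OdmStudy,
    protocol_meta: dict,
    cfg: Optional[MappingConfig] = None,
) -> ClinicalStudyPlan:
    """Build the plan from ODM metadata plus protocol registration fields.

    ODM carries none of the registration content (title, sponsor, dates,
    sample size, goals), so *protocol_meta* supplies it; a missing status
    is a hard error.  One activity per study event definition, referencing
    the event's Questionnaires; detail entries are derived from item
    groups routed to observations (hence the optional routing config).
    """
    if not protocol_meta.get("status"):
        raise ProtocolMetaError("protocol metadata must supply a status")
    cfg = cfg or MappingConfig()
    md = study.metadata

    activities: list[PlanActivity] = []
    for sed in md.study_event_defs.values():
        details: list[ActivityDetail] = []
        for foid in sed.form_refs:
            fd = md.form_defs.get(foid)
            if fd is None:
                continue
            for goid in fd.item_group_refs:
                igd = md.item_group_defs.get(goid)
                if igd is None or goid not in cfg.observation_groups:
                    continue
                parent_key = cfg.component_parents.get(goid)
                type_concept = (
                    bind_code(parent_key, None, cfg.code_map).to_json()
                    if parent_key
                    else {"text": igd.name}
                )
                details.append(
                    ActivityDetail(
                        category={"text": "observation"},
                        type=type_concept,
                        rationale=f"item group {igd.name} captured as observations",
                    )
                )
        activities.append(
            PlanActivity(
                scheduled=sed.event_type,
                action_resulting=[
                    ref("Questionnaire", f"questionnaire-{slug(foid)}")
                    for foid in sed.form_refs
                ],
                detail=details,
            )
        )

    contact = protocol_meta.get("publicContact")
    return ClinicalStudyPlan(
        identifier=protocol_meta.get("identifier", study.study_oid),
        external_identifier=protocol_meta.get("externalIdentifier"),
        title=protocol_meta.get("title", study.study_name),
        official_title=protocol_meta.get("officialTitle"),
        registration_date=protocol_meta.get("registrationDate"),
        authoring_body=protocol_meta.get("authoringBody"),
        status=protocol_meta["status"],
        sponsor=[
            {"display": s} if isinstance(s, str) else s
            for s in protocol_meta.get("sponsors") or []
        ],
        public_contact=(
            ContactDetail(
                name=contact.get("name"), telecom=contact.get("telecom") or []
            )
            if contact
            else None
        ),
        investigator=(
            {"display": protocol_meta["investigator"]}
            if isinstance(protocol_meta.get("investigator"), str)
            else protocol_meta.get("investigator")
        ),
        description=protocol_meta.get("description"),
        date_first_enrolment=protocol_meta.get("dateFirstEnrolment"),
        sample_size=protocol_meta.get("sampleSize"),
        goal=[Goal(**g) for g in protocol_meta.get("goals") or []],
        activity=activities,
        note=protocol_meta.get("note"),
    )


# ---------------------------------------------------------------------------
# ClinicalStudyData
# ---------------------------------------------------------------------------


class Investigations(BaseModel):
    """Choice of exactly one investigation kind per visit."""

    questionnaire_response: Optional[dict] = None
    observation: list[dict] = Field(default_factory=list)
    imaging_manifest: list[dict] = Field(default_factory=list)

    def kinds_present(self) -> list[str]:
        out = []
        if self.questionnaire_response is not None:
            out.append("questionnaireResponse")
        if self.observation:
            out.append("observation")
        if self.imaging_manifest:
            out.append("imagingManifest")
        return out

    def to_json(self) -> dict:
        out: dict = {}
        if self.questionnaire_response is not None:
            out["questionnaireResponse"] = self.questionnaire_response
        if self.observation:
            out["observation"] = self.observation
        if self.imaging_manifest:
            out["imagingManifest"] = self.imaging_manifest
        return out


class Visit(BaseModel):
    scheduled: Optional[str] = None  # planned | unplanned
    timing: Optional[str] = None
    investigations: Investigations = Field(default_factory=Investigations)


class Participant(BaseModel):
    role: Optional[dict] = None
    member: Optional[dict] = None


class StudyEvent(BaseModel):
    status: Optional[str] = None
    type: Optional[dict] = None
    participant: list[Participant] = Field(default_factory=list)
    summary: Optional[str] = None
    visit: list[Visit] = Field(default_factory=list)


class Period(BaseModel):
    start: Optional[str] = None
    end: Optional[str] = None


class StatusHistoryEntry(BaseModel):
    status: str
    period: Period


class ClinicalStudyData(BaseModel):
    identifier: Optional[str] = None
    external_identifier: Optional[str] = None
    patient: Optional[dict] = None
    plan: Optional[dict] = None
    status: Optional[str] = None
    status_history: list[StatusHistoryEntry] = Field(default_factory=list)
    period: Optional[Period] = None
    event: list[StudyEvent] = Field(default_factory=list)

    @property
    def resource_id(self) -> str:
        return f"studydata-{slug(self.identifier or 'subject')}"

    def to_resource(self) -> FhirResource:
        attrs: dict = {}
        if self.external_identifier is not None:
            attrs["externalIdentifier"] = self.external_identifier
        if self.patient is not None:
            attrs["patient"] = self.patient
        if self.plan is not None:
            attrs["plan"] = self.plan
        if self.status is not None:
            attrs["status"] = self.status
        if self.status_history:
            attrs["statusHistory"] = [
                {
                    "status": sh.status,
                    "period": {
                        k: v
                        for k, v in (("start", sh.period.start), ("end", sh.period.end))
                        if v is not None
                    },
                }
                for sh in self.status_history
            ]
        if self.period is not None:
            attrs["period"] = {
                k: v
                for k, v in (("start", self.period.start), ("end", self.period.end))
                if v is not None
            }
        if self.event:
            events = []
            for e in self.event:
                entry: dict = {}
                if e.status is not None:
                    entry["status"] = e.status
                if e.type is not None:
                    entry["type"] = e.type
                if e.participant:
                    entry["participant"] = [
                        {k: v for k, v in p.model_dump().items() if v is not None}
                        for p in e.participant
                    ]
                if e.summary is not None:
                    entry["summary"] = e.summary
                entry["visit"] = [
                    {
                        **({"scheduled": v.scheduled} if v.scheduled else {}),
                        **({"timing": v.timing} if v.timing else {}),
                        "investigations": v.investigations.to_json(),
                    }
                    for v in e.visit
                ]
                events.append(entry)
            attrs["event"] = events
        identifier = (
            [{"system": "urn:odmfhir:studydata", "value": self.identifier}]
            if self.identifier
            else []
        )
        return FhirResource(
            resource_type="ClinicalStudyData",
            id=self.resource_id,
            identifier=identifier,
            attrs=attrs,
        )


def _parse_instant(value: str) -> _dt.datetime:
    try:
        return _dt.datetime.fromisoformat(value)
    except ValueError:
        return _dt.datetime.combine(_dt.date.fromisoformat(value), _dt.time.min)


def validate_data(
    d: ClinicalStudyData, bundle: Optional[FhirBundle] = None
) -> list[Violation]:
    """Invariants: mandatory patient; investigations choice-of-one per
    visit; pairwise non-overlapping statusHistory periods (each closed
    except possibly the last); visit.scheduled in {planned, unplanned};
    patient/plan references resolvable when a bundle is supplied."""
    out: list[Violation] = []
    if d.patient is None or not d.patient.get("reference"):
        out.append(Violation("patient", "mandatory patient reference is missing"))
    elif bundle is not None:
        rtype, _, rid = d.patient["reference"].partition("/")
        if bundle.resource(rtype, rid) is None:
            out.append(
                Violation("patient", f"patient reference {d.patient['reference']!r} does not resolve")
            )
    if d.plan is not None and bundle is not None and d.plan.get("reference"):
        rtype, _, rid = d.plan["reference"].partition("/")
        if bundle.resource(rtype, rid) is None:
            out.append(Violation("plan", f"plan reference {d.plan['reference']!r} does not resolve"))

    entries = d.status_history
    parsed: list[tuple[Optional[_dt.datetime], Optional[_dt.datetime], int]] = []
    for i, sh in enumerate(entries):
        if sh.period.start is None:
            out.append(Violation(f"statusHistory[{i}].period", "period lacks a start"))
            continue
        start = _parse_instant(sh.period.start)
        end = _parse_instant(sh.period.end) if sh.period.end is not None else None
        parsed.append((start, end, i))
    parsed.sort(key=lambda t: t[0])
    for (s1, e1, i1), (s2, _e2, i2) in zip(parsed, parsed[1:]):
        if e1 is None:
            out.append(
                Violation(
                    f"statusHistory[{i1}].period",
                    "only the last status period may be open-ended",
                )
            )
        elif e1 > s2:
            out.append(
                Violation(
                    f"statusHistory[{i2}].period",
                    f"period overlaps the preceding status period (entry {i1})",
                )
            )

    for ei, e in enumerate(d.event):
        if e.status is not None and e.status not in EVENT_STATUSES:
            out.append(
                Violation(
                    f"event[{ei}].status",
                    f"unknown event status {e.status!r}; expected one of {EVENT_STATUSES}",
                )
            )
        for vi, v in enumerate(e.visit):
            vpath = f"event[{ei}].visit[{vi}]"
            if v.scheduled is not None and v.scheduled not in VISIT_SCHEDULED:
                out.append(
                    Violation(
                        f"{vpath}.scheduled",
                        f"visit.scheduled must be planned or unplanned, got {v.scheduled!r}",
                    )
                )
            kinds = v.investigations.kinds_present()
            if len(kinds) != 1:
                out.append(
                    Violation(
                        f"{vpath}.investigations",
                        "exactly one investigation kind required, "
                        f"found {kinds or 'none'}",
                    )
                )
            elif bundle is not None:
                refs = (
                    [v.investigations.questionnaire_response]
                    if v.investigations.questionnaire_response
                    else v.investigations.observation or v.investigations.imaging_manifest
                )
                for r in refs:
                    target = r.get("reference", "")
                    rtype, _, rid = target.partition("/")
                    if bundle.resource(rtype, rid) is None:
                        out.append(
                            Violation(
                                f"{vpath}.investigations",
                                f"investigation reference {target!r} does not resolve",
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# Building from ODM
# ---------------------------------------------------------------------------


@dataclass
class NativeBuildResult:
    data: ClinicalStudyData
    resources: list[FhirResource] = field(default_factory=list)
    ledger: LossLedger = field(default_factory=LossLedger)

    def __iter__(self):
        return iter((self.data, self.resources))


def build_data(
    study: OdmStudy,
    plan: ClinicalStudyPlan,
    cfg: MappingConfig,
    subject_key: str,
    ledger: Optional[LossLedger] = None,
) -> NativeBuildResult:
    """One subject's captured data as a ClinicalStudyData resource.

    Events group the subject's study-event occurrences by definition OID;
    each occurrence is one visit (planned for scheduled events, unplanned
    otherwise).  A visit's investigations honour the choice rule: all of a
    visit's leaves must route to Observations, or all to a single
    QuestionnaireResponse spanning the visit's forms — a mixed visit is a
    hard error naming the visit.  Referenced resources (Patient,
    Observations, QuestionnaireResponse, Practitioners) are returned
    alongside.
    """
    subj: SubjectData = study.subject(subject_key)
    validate_config(cfg, study)
    ledger = ledger if ledger is not None else LossLedger()
    dispositions: dict[str, str] = {}
    practitioners: dict[str, FhirResource] = {}
    resources: list[FhirResource] = []

    patient = build_patient(subj, study, cfg, ledger)
    resources.append(patient)
    subject_ref = ref(patient)

    by_event: dict[str, list[StudyEventData]] = {}
    for evt in subj.events:
        by_event.setdefault(evt.study_event_oid, []).append(evt)

    events: list[StudyEvent] = []
    for evt_oid, occurrences in by_event.items():
        sed = study.metadata.study_event_defs[evt_oid]
        visits: list[Visit] = []
        for evt in occurrences:
            rk = evt.repeat_key or "1"
            answer_groups: list[dict] = []
            observations: list[FhirResource] = []
            effective: Optional[str] = None
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
                    encounter_ref=None,
                )
                if fo.answer_groups:
                    answer_groups.append(
                        {"linkId": form_data.form_oid, "group": fo.answer_groups}
                    )
                observations.extend(fo.observations)
            if answer_groups and observations:
                raise InvestigationMixError(
                    f"visit {evt_oid}#{rk} of subject {subject_key} mixes "
                    "question answers and observations; a visit's investigations "
                    "must be exactly one kind"
                )
            inv = Investigations()
            if observations:
                resources.extend(observations)
                inv.observation = [ref(o) for o in observations]
                for o in observations:
                    effective = effective or o.attrs.get("effectiveTime") or o.attrs.get(
                        "effectiveDateTime"
                    )
            elif answer_groups:
                qr = FhirResource(
                    resource_type="QuestionnaireResponse",
                    id=f"response-{slug(subject_key, evt_oid, rk)}",
                    attrs={
                        "status": "completed",
                        "subject": subject_ref,
                        "group": {
                            "linkId": f"{evt_oid}.{rk}",
                            "group": answer_groups,
                        },
                    },
                )
                if len(evt.forms) == 1:
                    qr.attrs["questionnaire"] = ref(
                        "Questionnaire", f"questionnaire-{slug(evt.forms[0].form_oid)}"
                    )
                resources.append(qr)
                inv.questionnaire_response = ref(qr)
            visits.append(
                Visit(
                    scheduled="planned" if sed.event_type == "scheduled" else "unplanned",
                    timing=effective,
                    investigations=inv,
                )
            )
        events.append(
            StudyEvent(
                status="finished",
                type={"text": sed.name or evt_oid},
                summary=f"{len(visits)} visit(s) for event {sed.name or evt_oid}",
                visit=visits,
            )
        )

    data = ClinicalStudyData(
        identifier=f"{study.study_oid}-{subject_key}",
        patient=subject_ref,
        plan=ref("ClinicalStudyPlan", plan.resource_id),
        status="finished",
        event=events,
    )
    for pid in sorted(practitioners):
        resources.append(practitioners[pid])
    return NativeBuildResult(data=data, resources=resources, ledger=ledger)


def build_native_bundle(
    study: OdmStudy,
    protocol_meta: dict,
    cfg: MappingConfig,
) -> tuple[FhirBundle, LossLedger]:
    """Whole-study native bundle: plan, questionnaires, and per-subject
    ClinicalStudyData with all referenced resources."""
    validate_config(cfg, study)
    ledger = LossLedger()
    plan = build_plan(study, protocol_meta, cfg)
    bundle = FhirBundle()
    bundle.add(plan.to_resource())
    for fd in study.metadata.form_defs.values():
        bundle.add(map_form_def(fd, study.metadata, cfg))
    for subj in study.subjects:
        result = build_data(study, plan, cfg, subj.subject_key, ledger)
        for r in result.resources:
            # practitioners may recur across subjects; keep one copy
            if bundle.resource(r.resource_type, r.id) is None:
                bundle.add(r)
        bundle.add(result.data.to_resource())
    return bundle, ledger
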