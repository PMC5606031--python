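"""WHO Trial Registration Data Set coverage for ClinicalStudyPlan.

The WHO publishes twenty mandatory items a study protocol must declare for
the trial to be considered fully registered.  This module ships the
checklist with its static mapping onto ClinicalStudyPlan attributes and
reports coverage in two modes:

* ``structural`` — classifies by the static mapping alone (which items the
  resource *can* express); the result is constant across plans.
* ``instance``  — additionally requires the mapped attribute to be
  populated on the given plan.

Three items have no plan attribute at all: sources of monetary support and
countries of recruitment are clinical-trial concerns left out of the model,
and key inclusion/exclusion criteria await a machine-processable eligibility
representation.  Study type (item 15) is only implicitly addressed — the
resource inherently suggests a clinical study — so it reports as partial.
Items 5 and 6 (primary/secondary sponsor) both map to ``sponsor``; in
instance mode the secondary-sponsor item counts as satisfied only when at
least two sponsors are present, partial when exactly one.

The corresponding PlanDefinition column is shipped for documentation but
not evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Optional

from .study import ClinicalStudyPlan

Coverage = Literal["full", "partial", "none"]


@dataclass(frozen=True)
class ChecklistItem:
    index: int
    label: str
    plan_attribute: Optional[str]
    coverage: Coverage
    plan_definition_attribute: Optional[str] = None  # documentation only


_ITEMS: tuple[ChecklistItem, ...] = (
    ChecklistItem(1, "Primary registry and trial identifying number", "identifier", "full", "identifier"),
    ChecklistItem(2, "Date of registration in primary registry", "registrationDate", "full", None),
    ChecklistItem(3, "Secondary identifying numbers", "externalIdentifier", "full", "identifier"),
    ChecklistItem(4, "Source(s) of monetary or material support", None, "none", None),
    ChecklistItem(5, "Primary sponsor", "sponsor", "full", None),
    ChecklistItem(6, "Secondary sponsor(s)", "sponsor", "full", None),
    ChecklistItem(7, "Contact for public queries", "publicContact", "full", "publisher"),
    ChecklistItem(8, "Contact for scientific queries", "investigator", "full", None),
    ChecklistItem(9, "Public title", "title", "full", "title"),
    ChecklistItem(10, "Scientific title", "officialTitle", "full", None),
    ChecklistItem(11, "Countries of recruitment", None, "none", None),
    ChecklistItem(12, "Health condition(s) or problem(s) studied", "description", "full", "purpose*"),
    ChecklistItem(13, "Intervention(s)", "activity", "full", "actionDefinition"),
    ChecklistItem(14, "Key inclusion and exclusion criteria", None, "none", None),
    ChecklistItem(15, "Study type", None, "partial", "type*"),
    ChecklistItem(16, "Date of first enrolment", "dateFirstEnrolment", "full", None),
    ChecklistItem(17, "Target sample size", "sampleSize", "full", None),
    ChecklistItem(18, "Recruitment status", "status", "full", "status"),
    ChecklistItem(19, "Primary outcome(s)", "goal", "full", "coverage*"),
    ChecklistItem(20, "Key secondary outcomes", "goal", "full", "coverage*"),
)


@dataclass(frozen=True)
class WhoChecklist:
    items: tuple[ChecklistItem, ...]

    def __post_init__(self):
        assert len(self.items) == 20
        assert [i.index for i in self.items] == list(range(1, 21))

    def item(self, index: int) -> ChecklistItem:
        return self.items[index - 1]


def load_checklist() -> WhoChecklist:
    """The bundled 20-item WHO trial-registration checklist."""
    return WhoChecklist(items=_ITEMS)


@dataclass
class CoverageReport:
    """Partition of the 20 items into satisfied / partial / missing."""

    mode: str
    satisfied: set[int]
    partial: set[int]
    missing: set[int]
    per_item: list[dict]

    def to_json(self) -> str:
        doc = {
            "mode": self.mode,
            "satisfied": sorted(self.satisfied),
            "partial": sorted(self.partial),
            "missing": sorted(self.missing),
            "items": self.per_item,
        }
        return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"

    def to_text(self) -> str:
        lines = [
            f"WHO trial registration coverage ({self.mode} mode)",
            f"satisfied: {len(self.satisfied)}  partial: {len(self.partial)}  "
            f"missing: {len(self.missing)}",
            "",
        ]
        marks = {True: "", False: ""}
        for row in self.per_item:
            state = (
                "satisfied"
                if row["index"] in self.satisfied
                else "partial" if row["index"] in self.partial else "missing"
            )
            attr = row["attribute"] or "-"
            lines.append(
                f"{row['index']:>2}. {row['label']:<48} {attr:<20} "
                f"{marks[row['populated']]} {state}"
            )
        return "\n".join(lines) + "\n"


def _populated(plan: ClinicalStudyPlan, attribute: str) -> bool:
    value = {
        "identifier": plan.identifier,
        "externalIdentifier": plan.external_identifier,
        "registrationDate": plan.registration_date,
        "sponsor": plan.sponsor,
        "publicContact": (
            plan.public_contact
            and (plan.public_contact.name or plan.public_contact.telecom)
        ),
        "investigator": plan.investigator,
        "title": plan.title,
        "officialTitle": plan.official_title,
        "description": plan.description,
        "activity": plan.activity,
        "dateFirstEnrolment": plan.date_first_enrolment,
        "sampleSize": plan.sample_size,
        "status": plan.status,
        "goal": plan.goal,
    }[attribute]
    if attribute == "sampleSize":
        return value is not None and value > 0
    return bool(value)


def who_coverage(
    plan: ClinicalStudyPlan, mode: Literal["structural", "instance"] = "structural"
) -> CoverageReport:
    """Classify each WHO item for the given plan.

    The three sets always partition {1..20}.  Structural mode depends only
    on the checklist; instance mode additionally requires the mapped
    attribute to be populated (plans should pass ``validate_plan`` first).
    """
    checklist = load_checklist()
    satisfied: set[int] = set()
    partial: set[int] = set()
    missing: set[int] = set()
    per_item: list[dict] = []

    for item in checklist.items:
        populated = (
            _populated(plan, item.plan_attribute) if item.plan_attribute else False
        )
        if item.coverage == "none":
            missing.add(item.index)
        elif item.coverage == "partial":
            partial.add(item.index)
        elif mode == "structural":
            satisfied.add(item.index)
        else:  # instance mode, full mapping
            if not populated:
                missing.add(item.index)
            elif item.index == 6:
                # secondary sponsors need a second sponsor entry
                (satisfied if len(plan.sponsor) >= 2 else partial).add(item.index)
            else:
                satisfied.add(item.index)
        per_item.append(
            {
                "index": item.index,
                "label": item.label,
                "attribute": item.plan_attribute,
                "populated": populated,
            }
        )
    return CoverageReport(
        mode=mode, satisfied=satisfied, partial=partial, missing=missing, per_item=per_item
    )
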