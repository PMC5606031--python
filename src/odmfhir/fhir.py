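"""Generic FHIR resource envelope, bundles, validation, and JSON wire form.

The resource shapes are pinned to the "Standard for Trial Use 3" snapshot of
September 2016 and read from a versioned config file
(``data/fhir_shapes.yaml``); the FHIR specification of that era was openly
in flux, so the shape table is data, not code.

Design notes
------------
* Resource attributes (``FhirResource.attrs``) are plain JSON trees —
  dicts, lists, strings, numbers, booleans.  References are dicts with a
  ``reference`` key ("<ResourceType>/<id>"); codeable concepts are dicts
  with ``coding``/``text`` keys.  Keeping the in-memory form identical to
  the wire form makes serialization trivially injective and the round trip
  ``parse(serialize(b)) == b`` exact.
* JSON is the only wire form (stable key order, two-space indent), so equal
  bundles always serialize to identical bytes.
"""

from __future__ import annotations

import json
import re
from functools import lru_cache
from typing import Any, Iterator, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import SerializationRefusedError, Violation

SNOMED_URI = "http://snomed.info/sct"
LOINC_URI = "http://loinc.org"

_REFERENCE_RE = re.compile(r"^[A-Za-z]+/[A-Za-z0-9\-\.]{1,64}$")
_ID_RE = re.compile(r"^[A-Za-z0-9\-\.]{1,64}$")


@lru_cache(maxsize=1)
def resource_shapes() -> dict[str, Any]:
    """Load the versioned resource-shape table bundled with the package."""
    from importlib.resources import files

    text = files("odmfhir").joinpath("data/fhir_shapes.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def known_resource_types() -> set[str]:
    return set(resource_shapes()["resources"])


# ---------------------------------------------------------------------------
# Datatypes
# ---------------------------------------------------------------------------


class Coding(BaseModel):
    system: str
    code: str
    display: Optional[str] = None

    def to_json(self) -> dict:
        out = {"system": self.system, "code": self.code}
        if self.display is not None:
            out["display"] = self.display
        return out


class CodeableConcept(BaseModel):
    """One concept, coded in zero or more terminologies and/or as text.

    The usual invariant requires at least one coding or a text; an entirely
    empty concept is rejected.  A text-only concept (empty codings) is the
    sanctioned fallback when no code map entry exists.
    """

    codings: list[Coding] = Field(default_factory=list)
    text: Optional[str] = None

    @model_validator(mode="after")
    def _not_empty(self) -> "CodeableConcept":
        if not self.codings and self.text is None:
            raise ValueError("CodeableConcept needs at least one coding or a text")
        return self

    def to_json(self) -> dict:
        out: dict[str, Any] = {}
        if self.codings:
            out["coding"] = [c.to_json() for c in self.codings]
        if self.text is not None:
            out["text"] = self.text
        return out


class Reference(BaseModel):
    """A typed link "<ResourceType>/<id>" to another resource."""

    target: str
    display: Optional[str] = None

    @field_validator("target")
    @classmethod
    def _pattern(cls, v: str) -> str:
        if not _REFERENCE_RE.match(v):
            raise ValueError(f"reference {v!r} is not of form ResourceType/id")
        return v

    def to_json(self) -> dict:
        out = {"reference": self.target}
        if self.display is not None:
            out["display"] = self.display
        return out


def ref(resource_or_type, rid: str | None = None, display: str | None = None) -> dict:
    """Build a reference dict to a resource (or from explicit type + id)."""
    if rid is None:
        target = f"{resource_or_type.resource_type}/{resource_or_type.id}"
    else:
        target = f"{resource_or_type}/{rid}"
    out = {"reference": target}
    if display is not None:
        out["display"] = display
    return out


# ---------------------------------------------------------------------------
# Envelope
# ---------------------------------------------------------------------------


class FhirResource(BaseModel):
    resource_type: str
    id: str
    identifier: list[dict] = Field(default_factory=list)
    attrs: dict[str, Any] = Field(default_factory=dict)

    def to_json(self) -> dict:
        out: dict[str, Any] = {"resourceType": self.resource_type, "id": self.id}
        if self.identifier:
            out["identifier"] = self.identifier
        out.update(self.attrs)
        return out

    @classmethod
    def from_json(cls, data: dict) -> "FhirResource":
        data = dict(data)
        rtype = data.pop("resourceType")
        rid = data.pop("id")
        identifier = data.pop("identifier", [])
        return cls(resource_type=rtype, id=rid, identifier=identifier, attrs=data)


class FhirBundle(BaseModel):
    entries: list[FhirResource] = Field(default_factory=list)

    def add(self, resource: FhirResource) -> FhirResource:
        self.entries.append(resource)
        return resource

    def resource(self, resource_type: str, rid: str) -> Optional[FhirResource]:
        for r in self.entries:
            if r.resource_type == resource_type and r.id == rid:
                return r
        return None

    def by_type(self, resource_type: str) -> list[FhirResource]:
        return [r for r in self.entries if r.resource_type == resource_type]

    def resource_types(self) -> set[str]:
        return {r.resource_type for r in self.entries}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _iter_references(node: Any, path: str) -> Iterator[tuple[str, str]]:
    """Yield ``(path, target)`` for every reference dict under *node*."""
    if isinstance(node, dict):
        if "reference" in node and isinstance(node["reference"], str):
            yield path, node["reference"]
        for key, value in node.items():
            if key != "reference":
                yield from _iter_references(value, f"{path}.{key}")
    elif isinstance(node, list):
        for i, value in enumerate(node):
            yield from _iter_references(value, f"{path}[{i}]")


def _walk_group_tree(node: dict, path: str, out: list[Violation]) -> None:
    """Questionnaire/QuestionnaireResponse rule: a group node defines either
    subgroups or questions, never both."""
    has_groups = bool(node.get("group"))
    has_questions = bool(node.get("question"))
    if has_groups and has_questions:
        out.append(Violation(path, "group defines both subgroups and questions"))
    for i, sub in enumerate(node.get("group") or []):
        _walk_group_tree(sub, f"{path}.group[{i}]", out)


def validate_resource(resource: FhirResource) -> list[Violation]:
    """Check the per-type invariants of one resource.

    Returns violations naming the offending attribute path; an empty list
    means the resource is valid against its pinned shape.
    """
    out: list[Violation] = []
    base = f"{resource.resource_type}/{resource.id}"
    shapes = resource_shapes()["resources"]

    if resource.resource_type not in shapes:
        out.append(
            Violation(base, f"unknown resource type {resource.resource_type!r}")
        )
        return out
    if not _ID_RE.match(resource.id):
        out.append(Violation(base, f"invalid resource id {resource.id!r}"))

    allowed = set(shapes[resource.resource_type].get("attributes") or [])
    for key in resource.attrs:
        if key not in allowed:
            out.append(Violation(f"{base}.{key}", "attribute not in resource shape"))

    for path, target in _iter_references(resource.attrs, base):
        if not _REFERENCE_RE.match(target):
            out.append(Violation(path, f"malformed reference {target!r}"))

    if resource.resource_type in ("Questionnaire", "QuestionnaireResponse"):
        root = resource.attrs.get("group")
        if isinstance(root, dict):
            _walk_group_tree(root, f"{base}.group", out)
        elif isinstance(root, list):
            for i, node in enumerate(root):
                _walk_group_tree(node, f"{base}.group[{i}]", out)

    if resource.resource_type == "Observation":
        value_keys = [k for k in resource.attrs if k.startswith("value")]
        if len(value_keys) > 1:
            out.append(
                Violation(base, f"multiple value[x] attributes: {sorted(value_keys)}")
            )
        for i, comp in enumerate(resource.attrs.get("component") or []):
            if "code" not in comp:
                out.append(Violation(f"{base}.component[{i}]", "component lacks a code"))
    return out


def validate_bundle(bundle: FhirBundle) -> list[Violation]:
    """Per-resource invariants plus id uniqueness and reference closure.

    Every dangling reference yields one violation carrying the source path
    and the unresolved target string.
    """
    out: list[Violation] = []
    index: set[tuple[str, str]] = set()
    for r in bundle.entries:
        key = (r.resource_type, r.id)
        if key in index:
            out.append(
                Violation(f"{r.resource_type}/{r.id}", "duplicate id within resource type")
            )
        index.add(key)
        out.extend(validate_resource(r))
    for r in bundle.entries:
        base = f"{r.resource_type}/{r.id}"
        for path, target in _iter_references(r.attrs, base):
            if not _REFERENCE_RE.match(target):
                continue  # already reported by validate_resource
            rtype, rid = target.split("/", 1)
            if (rtype, rid) not in index:
                out.append(Violation(path, f"dangling reference {target!r}"))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def serialize_bundle(bundle: FhirBundle) -> str:
    """Deterministic JSON for a valid bundle.

    Key order and entry order are stable, so equal bundles produce
    byte-identical output.  Refuses to serialize an invalid bundle.
    """
    violations = validate_bundle(bundle)
    if violations:
        raise SerializationRefusedError(violations)
    doc = {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r.to_json()} for r in bundle.entries],
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def serialize_ndjson(bundle: FhirBundle) -> str:
    """One resource per line, compact deterministic JSON."""
    violations = validate_bundle(bundle)
    if violations:
        raise SerializationRefusedError(violations)
    return "".join(
        json.dumps(r.to_json(), sort_keys=True, separators=(",", ":"), ensure_ascii=False)
        + "\n"
        for r in bundle.entries
    )


def parse_bundle(text: str) -> FhirBundle:
    doc = json.loads(text)
    if doc.get("resourceType") != "Bundle":
        raise ValueError("not a FHIR Bundle document")
    return FhirBundle(
        entries=[FhirResource.from_json(e["resource"]) for e in doc.get("entry", [])]
    )
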