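"""CDISC ODM 1.3 documents: parsing, validation, and serialization.

An ODM document carries two parallel hierarchies — a *metadata* hierarchy
(StudyEventDef / FormDef / ItemGroupDef / ItemDef / CodeList) that defines
the structure of the study, and a *clinical data* hierarchy
(SubjectData / StudyEventData / FormData / ItemGroupData / ItemData) that
holds the captured values.  The two sides are joined by shared object
identifiers (OIDs): every data node names the OID of its definition.

This module pins the dialect to ODM 1.3 (namespace
``http://www.cdisc.org/ns/odm/v1.3``); documents in any other namespace are
rejected with a clear message.  The datatype vocabulary is restricted to the
seven tokens ``text, integer, float, date, time, datetime, boolean`` —
unknown tokens are hard errors rather than passthrough, so that downstream
loss accounting starts from a known vocabulary.

Elements outside the supported model (audit trails, vendor extensions) are
preserved verbatim as opaque attachments (``extras``) on the nearest typed
node; the mapping engine surfaces them to its loss ledger.
"""

from __future__ import annotations

import copy
import datetime as _dt
import re
from decimal import Decimal, InvalidOperation
from typing import Literal, Optional

from lxml import etree
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import (
    DanglingOidError,
    OdmParseError,
    OdmStructureError,
    OdmVocabularyError,
    Violation,
)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
ODM_VERSION = "1.3.2"

DATATYPES = ("text", "integer", "float", "date", "time", "datetime", "boolean")
NUMERIC_DATATYPES = ("integer", "float")
COMPARATORS = ("LT", "LE", "GT", "GE", "EQ", "NE")

Datatype = Literal["text", "integer", "float", "date", "time", "datetime", "boolean"]
Comparator = Literal["LT", "LE", "GT", "GE", "EQ", "NE"]


def _q(tag: str) -> str:
    return f"{{{ODM_NS}}}{tag}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class RangeCheck(BaseModel):
    comparator: Comparator
    bound: Decimal


class CodeListItem(BaseModel):
    coded_value: str
    decode: Optional[str] = None


class CodeList(BaseModel):
    oid: str
    name: str
    datatype: Datatype = "text"
    items: list[CodeListItem] = Field(default_factory=list)

    def coded_values(self) -> list[str]:
        return [i.coded_value for i in self.items]

    def decode(self, raw: str) -> Optional[str]:
        for i in self.items:
            if i.coded_value == raw:
                return i.decode
        return None


class ItemDef(BaseModel):
    """Definition of one question/measurement: datatype, size, unit, range, code list."""

    oid: str
    name: str
    question: Optional[str] = None
    datatype: Datatype
    length: Optional[int] = Field(default=None, gt=0)
    significant_digits: Optional[int] = Field(default=None, ge=0)
    measurement_unit: Optional[str] = None
    range_checks: list[RangeCheck] = Field(default_factory=list)
    code_list_oid: Optional[str] = None
    extras: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _constraint_applicability(self) -> "ItemDef":
        if self.significant_digits is not None and self.datatype != "float":
            raise ValueError(
                f"ItemDef {self.oid}: significantDigits only applies to float items"
            )
        if self.range_checks and self.datatype not in NUMERIC_DATATYPES:
            raise ValueError(
                f"ItemDef {self.oid}: range checks only apply to numeric items"
            )
        return self


class ItemGroupDef(BaseModel):
    oid: str
    name: str
    repeating: bool = False
    item_refs: list[str] = Field(default_factory=list)


class FormDef(BaseModel):
    oid: str
    name: str
    item_group_refs: list[str] = Field(default_factory=list)


class StudyEventDef(BaseModel):
    oid: str
    name: str
    event_type: Literal["scheduled", "unscheduled"] = "scheduled"
    repeating: bool = False
    form_refs: list[str] = Field(default_factory=list)


class MetaDataVersion(BaseModel):
    """Keyed definition collections; insertion order preserves document order."""

    oid: str
    name: str = "Metadata"
    study_event_defs: dict[str, StudyEventDef] = Field(default_factory=dict)
    form_defs: dict[str, FormDef] = Field(default_factory=dict)
    item_group_defs: dict[str, ItemGroupDef] = Field(default_factory=dict)
    item_defs: dict[str, ItemDef] = Field(default_factory=dict)
    code_lists: dict[str, CodeList] = Field(default_factory=dict)
    extras: list[str] = Field(default_factory=list)


class ItemData(BaseModel):
    item_oid: str
    value: str


class ItemGroupData(BaseModel):
    item_group_oid: str
    repeat_key: Optional[str] = None
    items: list[ItemData] = Field(default_factory=list)


class FormData(BaseModel):
    form_oid: str
    item_groups: list[ItemGroupData] = Field(default_factory=list)


class StudyEventData(BaseModel):
    study_event_oid: str
    repeat_key: Optional[str] = None
    forms: list[FormData] = Field(default_factory=list)


class SubjectData(BaseModel):
    subject_key: str
    events: list[StudyEventData] = Field(default_factory=list)
    extras: list[str] = Field(default_factory=list)


class OdmStudy(BaseModel):
    """One ODM document in memory: definitions plus clinical data, joined by OIDs."""

    study_oid: str
    study_name: str = ""
    protocol_name: str = ""
    metadata: MetaDataVersion
    subjects: list[SubjectData] = Field(default_factory=list)
    extras: list[str] = Field(default_factory=list)

    @field_validator("study_oid")
    @classmethod
    def _non_empty_oid(cls, v: str) -> str:
        if not v:
            raise ValueError("studyOid must be non-empty")
        return v

    def subject(self, key: str) -> SubjectData:
        for s in self.subjects:
            if s.subject_key == key:
                return s
        raise KeyError(f"no subject with key {key!r}")

    def iter_leaves(self):
        """Yield ``(path, StudyEventData, FormData, ItemGroupData, ItemData)``
        for every ItemData leaf, in document order."""
        for subj in self.subjects:
            for evt in subj.events:
                for form in evt.forms:
                    for grp in form.item_groups:
                        for item in grp.items:
                            yield (
                                leaf_path(subj.subject_key, evt, form, grp, item),
                                subj,
                                evt,
                                form,
                                grp,
                                item,
                            )


def event_path(subject_key: str, evt: StudyEventData) -> str:
    rk = evt.repeat_key or "1"
    return f"subject[{subject_key}]/event[{evt.study_event_oid}#{rk}]"


def leaf_path(
    subject_key: str,
    evt: StudyEventData,
    form: FormData,
    grp: ItemGroupData,
    item: ItemData,
) -> str:
    return (
        f"{event_path(subject_key, evt)}/form[{form.form_oid}]"
        f"/group[{grp.item_group_oid}]/item[{item.item_oid}]"
    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _canon_xml(el: etree._Element) -> str:
    """Serialize an opaque extension element with whitespace normalized, so
    the representation is stable under re-indentation."""
    el = copy.deepcopy(el)
    for node in el.iter():
        if node.text is not None and not node.text.strip():
            node.text = None
        if node.tail is not None:
            node.tail = None
    return etree.tostring(el, encoding="unicode")


def _text_of(parent: etree._Element, tag: str) -> str:
    el = parent.find(_q(tag))
    if el is None:
        return ""
    # StudyName/ProtocolName hold text directly; TranslatedText children
    # are used inside Question/Decode.
    return (el.text or "").strip()


def _translated_text(el: etree._Element) -> Optional[str]:
    tt = el.find(_q("TranslatedText"))
    if tt is not None:
        return (tt.text or "").strip()
    return (el.text or "").strip() or None


def _yesno(value: str | None, default: bool = False) -> bool:
    if value is None:
        return default
    return value.strip().lower() == "yes"


def _children(el: etree._Element):
    for child in el:
        if isinstance(child.tag, str):  # skip comments / PIs
            yield child


def _unique_insert(coll: dict, oid: str, obj, what: str) -> None:
    if oid in coll:
        raise OdmStructureError(f"duplicate {what} OID {oid!r}")
    coll[oid] = obj


def _parse_item_def(el: etree._Element) -> ItemDef:
    oid = el.get("OID") or ""
    datatype = el.get("DataType") or ""
    if datatype not in DATATYPES:
        raise OdmVocabularyError(
            f"ItemDef {oid!r}: unknown datatype token {datatype!r}; "
            f"supported: {', '.join(DATATYPES)}"
        )
    question = None
    unit = None
    checks: list[RangeCheck] = []
    code_list_oid = None
    extras: list[str] = []
    for child in _children(el):
        tag = etree.QName(child).localname
        if tag == "Question":
            question = _translated_text(child)
        elif tag == "MeasurementUnitRef":
            unit = child.get("MeasurementUnitOID")
        elif tag == "RangeCheck":
            comp = child.get("Comparator") or ""
            if comp not in COMPARATORS:
                raise OdmVocabularyError(
                    f"ItemDef {oid!r}: unknown range-check comparator {comp!r}"
                )
            cv = child.find(_q("CheckValue"))
            raw_bound = (cv.text or "").strip() if cv is not None else ""
            try:
                bound = Decimal(raw_bound)
            except InvalidOperation as exc:
                raise OdmStructureError(
                    f"ItemDef {oid!r}: non-numeric range-check bound {raw_bound!r}"
                ) from exc
            checks.append(RangeCheck(comparator=comp, bound=bound))
        elif tag == "CodeListRef":
            code_list_oid = child.get("CodeListOID")
        else:
            extras.append(_canon_xml(child))
    length = el.get("Length")
    sig = el.get("SignificantDigits")
    try:
        return ItemDef(
            oid=oid,
            name=el.get("Name") or oid,
            question=question,
            datatype=datatype,
            length=int(length) if length else None,
            significant_digits=int(sig) if sig else None,
            measurement_unit=unit,
            range_checks=checks,
            code_list_oid=code_list_oid,
            extras=extras,
        )
    except ValueError as exc:
        raise OdmStructureError(str(exc)) from exc


def _parse_metadata(el: etree._Element) -> MetaDataVersion:
    md = MetaDataVersion(oid=el.get("OID") or "MDV.1", name=el.get("Name") or "Metadata")
    for child in _children(el):
        tag = etree.QName(child).localname
        if tag == "StudyEventDef":
            type_attr = (child.get("Type") or "Scheduled").strip().lower()
            if type_attr not in ("scheduled", "unscheduled"):
                raise OdmVocabularyError(
                    f"StudyEventDef {child.get('OID')!r}: unknown Type {child.get('Type')!r}"
                )
            sed = StudyEventDef(
                oid=child.get("OID") or "",
                name=child.get("Name") or "",
                event_type=type_attr,
                repeating=_yesno(child.get("Repeating")),
                form_refs=[
                    fr.get("FormOID") or "" for fr in child.findall(_q("FormRef"))
                ],
            )
            _unique_insert(md.study_event_defs, sed.oid, sed, "StudyEventDef")
        elif tag == "FormDef":
            fd = FormDef(
                oid=child.get("OID") or "",
                name=child.get("Name") or "",
                item_group_refs=[
                    r.get("ItemGroupOID") or ""
                    for r in child.findall(_q("ItemGroupRef"))
                ],
            )
            _unique_insert(md.form_defs, fd.oid, fd, "FormDef")
        elif tag == "ItemGroupDef":
            igd = ItemGroupDef(
                oid=child.get("OID") or "",
                name=child.get("Name") or "",
                repeating=_yesno(child.get("Repeating")),
                item_refs=[
                    r.get("ItemOID") or "" for r in child.findall(_q("ItemRef"))
                ],
            )
            _unique_insert(md.item_group_defs, igd.oid, igd, "ItemGroupDef")
        elif tag == "ItemDef":
            idf = _parse_item_def(child)
            _unique_insert(md.item_defs, idf.oid, idf, "ItemDef")
        elif tag == "CodeList":
            cl_datatype = child.get("DataType") or "text"
            if cl_datatype not in DATATYPES:
                raise OdmVocabularyError(
                    f"CodeList {child.get('OID')!r}: unknown datatype {cl_datatype!r}"
                )
            cl = CodeList(
                oid=child.get("OID") or "",
                name=child.get("Name") or "",
                datatype=cl_datatype,
                items=[
                    CodeListItem(
                        coded_value=ci.get("CodedValue") or "",
                        decode=(
                            _translated_text(ci.find(_q("Decode")))
                            if ci.find(_q("Decode")) is not None
                            else None
                        ),
                    )
                    for ci in child.findall(_q("CodeListItem"))
                ],
            )
            _unique_insert(md.code_lists, cl.oid, cl, "CodeList")
        else:
            md.extras.append(_canon_xml(child))
    return md


def _parse_subject(el: etree._Element) -> SubjectData:
    subj = SubjectData(subject_key=el.get("SubjectKey") or "")
    for sed in _children(el):
        if etree.QName(sed).localname != "StudyEventData":
            subj.extras.append(_canon_xml(sed))
            continue
        evt = StudyEventData(
            study_event_oid=sed.get("StudyEventOID") or "",
            repeat_key=sed.get("StudyEventRepeatKey"),
        )
        for fd in sed.findall(_q("FormData")):
            form = FormData(form_oid=fd.get("FormOID") or "")
            for igd in fd.findall(_q("ItemGroupData")):
                grp = ItemGroupData(
                    item_group_oid=igd.get("ItemGroupOID") or "",
                    repeat_key=igd.get("ItemGroupRepeatKey"),
                )
                for idt in igd.findall(_q("ItemData")):
                    grp.items.append(
                        ItemData(
                            item_oid=idt.get("ItemOID") or "",
                            value=idt.get("Value") or "",
                        )
                    )
                form.item_groups.append(grp)
            evt.forms.append(form)
        subj.events.append(evt)
    return subj


def read_odm(xml_text: str | bytes) -> OdmStudy:
    """Parse an ODM 1.3 XML document into a fully linked :class:`OdmStudy`.

    Collection order follows document order throughout.  Raises
    :class:`OdmParseError` (with line number) for malformed XML,
    :class:`OdmStructureError` for structurally unusable documents, and
    :class:`OdmVocabularyError` for unknown datatype tokens.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text, parser=etree.XMLParser(remove_comments=True))
    except etree.XMLSyntaxError as exc:
        raise OdmParseError(f"malformed XML: {exc}", line=exc.lineno) from exc

    qname = etree.QName(root)
    if qname.localname != "ODM":
        raise OdmStructureError(f"root element is {qname.localname!r}, expected ODM")
    if qname.namespace != ODM_NS:
        raise OdmStructureError(
            f"unsupported ODM namespace {qname.namespace!r}; only 1.3 "
            f"({ODM_NS}) is supported"
        )

    study_el = root.find(_q("Study"))
    if study_el is None:
        raise OdmStructureError("document has no Study element")

    gv = study_el.find(_q("GlobalVariables"))
    study_name = _text_of(gv, "StudyName") if gv is not None else ""
    protocol_name = _text_of(gv, "ProtocolName") if gv is not None else ""

    md_el = study_el.find(_q("MetaDataVersion"))
    if md_el is None:
        raise OdmStructureError("Study has no MetaDataVersion element")
    metadata = _parse_metadata(md_el)

    study = OdmStudy(
        study_oid=study_el.get("OID") or "",
        study_name=study_name,
        protocol_name=protocol_name,
        metadata=metadata,
    )
    if not study_el.get("OID"):
        raise OdmStructureError("Study element lacks an OID attribute")

    seen_keys: set[str] = set()
    for cd in root.findall(_q("ClinicalData")):
        for sd in cd.findall(_q("SubjectData")):
            subj = _parse_subject(sd)
            if subj.subject_key in seen_keys:
                raise OdmStructureError(
                    f"duplicate SubjectKey {subj.subject_key!r}"
                )
            seen_keys.add(subj.subject_key)
            study.subjects.append(subj)

    for child in _children(root):
        tag = etree.QName(child).localname
        if tag not in ("Study", "ClinicalData"):
            study.extras.append(_canon_xml(child))
    return study


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _append_extras(parent: etree._Element, extras: list[str]) -> None:
    for snippet in extras:
        parent.append(etree.fromstring(snippet))


def write_odm(study: OdmStudy) -> str:
    """Serialize a study to namespaced ODM 1.3 XML.

    Output bytes are deterministic for equal inputs.  Refuses (with
    :class:`DanglingOidError`) to serialize a study whose OID references do
    not resolve.
    """
    violations = validate_referential_integrity(study)
    if violations:
        v = violations[0]
        raise DanglingOidError(
            f"study has {len(violations)} unresolved OID reference(s); "
            f"first: {v.path}: {v.message}"
        )

    root = etree.Element(_q("ODM"), nsmap={None: ODM_NS})
    root.set("FileOID", f"{study.study_oid}.file")
    root.set("FileType", "Snapshot")
    # Fixed creation stamp: serialization is content-addressed, not clocked.
    root.set("CreationDateTime", "1970-01-01T00:00:00")
    root.set("ODMVersion", ODM_VERSION)

    study_el = etree.SubElement(root, _q("Study"), OID=study.study_oid)
    gv = etree.SubElement(study_el, _q("GlobalVariables"))
    etree.SubElement(gv, _q("StudyName")).text = study.study_name
    etree.SubElement(gv, _q("ProtocolName")).text = study.protocol_name

    md = study.metadata
    md_el = etree.SubElement(study_el, _q("MetaDataVersion"), OID=md.oid, Name=md.name)
    for sed in md.study_event_defs.values():
        sed_el = etree.SubElement(
            md_el,
            _q("StudyEventDef"),
            OID=sed.oid,
            Name=sed.name,
            Repeating="Yes" if sed.repeating else "No",
            Type=sed.event_type.capitalize(),
        )
        for fref in sed.form_refs:
            etree.SubElement(sed_el, _q("FormRef"), FormOID=fref, Mandatory="Yes")
    for fd in md.form_defs.values():
        fd_el = etree.SubElement(
            md_el, _q("FormDef"), OID=fd.oid, Name=fd.name, Repeating="No"
        )
        for gref in fd.item_group_refs:
            etree.SubElement(
                fd_el, _q("ItemGroupRef"), ItemGroupOID=gref, Mandatory="Yes"
            )
    for igd in md.item_group_defs.values():
        igd_el = etree.SubElement(
            md_el,
            _q("ItemGroupDef"),
            OID=igd.oid,
            Name=igd.name,
            Repeating="Yes" if igd.repeating else "No",
        )
        for iref in igd.item_refs:
            etree.SubElement(igd_el, _q("ItemRef"), ItemOID=iref, Mandatory="Yes")
    for idf in md.item_defs.values():
        attrs = {"OID": idf.oid, "Name": idf.name, "DataType": idf.datatype}
        if idf.length is not None:
            attrs["Length"] = str(idf.length)
        if idf.significant_digits is not None:
            attrs["SignificantDigits"] = str(idf.significant_digits)
        idf_el = etree.SubElement(md_el, _q("ItemDef"), **attrs)
        if idf.question is not None:
            q_el = etree.SubElement(idf_el, _q("Question"))
            tt = etree.SubElement(q_el, _q("TranslatedText"))
            tt.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
            tt.text = idf.question
        if idf.measurement_unit is not None:
            etree.SubElement(
                idf_el, _q("MeasurementUnitRef"), MeasurementUnitOID=idf.measurement_unit
            )
        for rc in idf.range_checks:
            rc_el = etree.SubElement(
                idf_el, _q("RangeCheck"), Comparator=rc.comparator, SoftHard="Hard"
            )
            etree.SubElement(rc_el, _q("CheckValue")).text = str(rc.bound)
        if idf.code_list_oid is not None:
            etree.SubElement(idf_el, _q("CodeListRef"), CodeListOID=idf.code_list_oid)
        _append_extras(idf_el, idf.extras)
    for cl in md.code_lists.values():
        cl_el = etree.SubElement(
            md_el, _q("CodeList"), OID=cl.oid, Name=cl.name, DataType=cl.datatype
        )
        for ci in cl.items:
            ci_el = etree.SubElement(cl_el, _q("CodeListItem"), CodedValue=ci.coded_value)
            if ci.decode is not None:
                dec = etree.SubElement(ci_el, _q("Decode"))
                tt = etree.SubElement(dec, _q("TranslatedText"))
                tt.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
                tt.text = ci.decode
    _append_extras(md_el, md.extras)

    if study.subjects:
        cd_el = etree.SubElement(
            root, _q("ClinicalData"), StudyOID=study.study_oid, MetaDataVersionOID=md.oid
        )
        for subj in study.subjects:
            sd_el = etree.SubElement(cd_el, _q("SubjectData"), SubjectKey=subj.subject_key)
            for evt in subj.events:
                attrs = {"StudyEventOID": evt.study_event_oid}
                if evt.repeat_key is not None:
                    attrs["StudyEventRepeatKey"] = evt.repeat_key
                evt_el = etree.SubElement(sd_el, _q("StudyEventData"), **attrs)
                for form in evt.forms:
                    form_el = etree.SubElement(evt_el, _q("FormData"), FormOID=form.form_oid)
                    for grp in form.item_groups:
                        gattrs = {"ItemGroupOID": grp.item_group_oid}
                        if grp.repeat_key is not None:
                            gattrs["ItemGroupRepeatKey"] = grp.repeat_key
                        grp_el = etree.SubElement(form_el, _q("ItemGroupData"), **gattrs)
                        for item in grp.items:
                            etree.SubElement(
                                grp_el,
                                _q("ItemData"),
                                ItemOID=item.item_oid,
                                Value=item.value,
                            )
            _append_extras(sd_el, subj.extras)
    _append_extras(root, study.extras)

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# Referential integrity
# ---------------------------------------------------------------------------


def validate_referential_integrity(study: OdmStudy) -> list[Violation]:
    """Check OID closure across both hierarchies.

    Returns an empty list iff every metadata-side Ref and every data-side
    OID resolves to a definition.  Each violation names the source path and
    the missing OID; violations are data, never exceptions.
    """
    md = study.metadata
    out: list[Violation] = []

    for sed in md.study_event_defs.values():
        for fref in sed.form_refs:
            if fref not in md.form_defs:
                out.append(
                    Violation(
                        f"metadata/studyEventDef[{sed.oid}]/formRef",
                        f"missing FormDef {fref!r}",
                    )
                )
    for fd in md.form_defs.values():
        for gref in fd.item_group_refs:
            if gref not in md.item_group_defs:
                out.append(
                    Violation(
                        f"metadata/formDef[{fd.oid}]/itemGroupRef",
                        f"missing ItemGroupDef {gref!r}",
                    )
                )
    for igd in md.item_group_defs.values():
        for iref in igd.item_refs:
            if iref not in md.item_defs:
                out.append(
                    Violation(
                        f"metadata/itemGroupDef[{igd.oid}]/itemRef",
                        f"missing ItemDef {iref!r}",
                    )
                )
    for idf in md.item_defs.values():
        if idf.code_list_oid is not None and idf.code_list_oid not in md.code_lists:
            out.append(
                Violation(
                    f"metadata/itemDef[{idf.oid}]/codeListRef",
                    f"missing CodeList {idf.code_list_oid!r}",
                )
            )

    for subj in study.subjects:
        for evt in subj.events:
            epath = event_path(subj.subject_key, evt)
            if evt.study_event_oid not in md.study_event_defs:
                out.append(
                    Violation(epath, f"missing StudyEventDef {evt.study_event_oid!r}")
                )
            for form in evt.forms:
                fpath = f"{epath}/form[{form.form_oid}]"
                if form.form_oid not in md.form_defs:
                    out.append(Violation(fpath, f"missing FormDef {form.form_oid!r}"))
                for grp in form.item_groups:
                    gpath = f"{fpath}/group[{grp.item_group_oid}]"
                    if grp.item_group_oid not in md.item_group_defs:
                        out.append(
                            Violation(
                                gpath, f"missing ItemGroupDef {grp.item_group_oid!r}"
                            )
                        )
                    for item in grp.items:
                        if item.item_oid not in md.item_defs:
                            out.append(
                                Violation(
                                    f"{gpath}/item[{item.item_oid}]",
                                    f"missing ItemDef {item.item_oid!r}",
                                )
                            )
    return out


# ---------------------------------------------------------------------------
# Value validation
# ---------------------------------------------------------------------------


class ValueCheck(BaseModel):
    """Outcome of validating one raw value against its ItemDef."""

    value: object = None
    violations: list[Violation] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


_INT_RE = re.compile(r"[+-]?\d+\Z")
_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}
_COMPARE = {
    "LT": lambda v, b: v < b,
    "LE": lambda v, b: v <= b,
    "GT": lambda v, b: v > b,
    "GE": lambda v, b: v >= b,
    "EQ": lambda v, b: v == b,
    "NE": lambda v, b: v != b,
}


def _parse_typed(datatype: str, raw: str):
    """Parse raw text per ODM datatype; raise ValueError on failure."""
    if datatype == "text":
        return raw
    if datatype == "integer":
        if not _INT_RE.match(raw.strip()):
            raise ValueError(f"not an integer: {raw!r}")
        return int(raw)
    if datatype == "float":
        try:
            return Decimal(raw.strip())
        except InvalidOperation as exc:
            raise ValueError(f"not a float: {raw!r}") from exc
    if datatype == "date":
        return _dt.date.fromisoformat(raw.strip())
    if datatype == "time":
        return _dt.time.fromisoformat(raw.strip())
    if datatype == "datetime":
        return _dt.datetime.fromisoformat(raw.strip())
    if datatype == "boolean":
        token = raw.strip().lower()
        if token not in _BOOL_TOKENS:
            raise ValueError(f"not a boolean: {raw!r}")
        return _BOOL_TOKENS[token]
    raise ValueError(f"unknown datatype {datatype!r}")


def validate_item_value(
    item_def: ItemDef, raw: str, code_lists: dict[str, CodeList] | None = None
) -> ValueCheck:
    """Validate one raw value against its definition.

    Checks, in order: datatype parse, length, significant digits, every
    range check, and code-list membership.  Never throws; problems are
    returned as violations carrying the failed comparator/bound or the
    code-list mismatch.
    """
    code_lists = code_lists or {}
    path = f"itemDef[{item_def.oid}]"
    try:
        typed = _parse_typed(item_def.datatype, raw)
    except ValueError as exc:
        return ValueCheck(
            value=None, violations=[Violation(path, f"datatype {item_def.datatype}: {exc}")]
        )

    violations: list[Violation] = []
    if item_def.length is not None:
        if item_def.datatype == "integer":
            measured = len(str(abs(typed)))
        elif item_def.datatype == "float":
            measured = sum(c.isdigit() for c in raw)
        else:
            measured = len(raw)
        if measured > item_def.length:
            violations.append(
                Violation(path, f"length {measured} exceeds declared length {item_def.length}")
            )
    if item_def.significant_digits is not None and item_def.datatype == "float":
        exponent = typed.as_tuple().exponent
        decimals = -exponent if isinstance(exponent, int) and exponent < 0 else 0
        if decimals > item_def.significant_digits:
            violations.append(
                Violation(
                    path,
                    f"{decimals} decimal digits exceed significantDigits "
                    f"{item_def.significant_digits}",
                )
            )
    if item_def.datatype in NUMERIC_DATATYPES:
        numeric = Decimal(typed) if isinstance(typed, int) else typed
        for rc in item_def.range_checks:
            if not _COMPARE[rc.comparator](numeric, rc.bound):
                violations.append(
                    Violation(path, f"range check {rc.comparator} {rc.bound} failed for {raw!r}")
                )
    if item_def.code_list_oid is not None:
        cl = code_lists.get(item_def.code_list_oid)
        if cl is None:
            violations.append(
                Violation(path, f"code list {item_def.code_list_oid!r} not found")
            )
        elif raw not in cl.coded_values():
            violations.append(
                Violation(
                    path,
                    f"value {raw!r} not in code list {item_def.code_list_oid!r} "
                    f"({', '.join(cl.coded_values())})",
                )
            )
    return ValueCheck(value=typed, violations=violations)
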