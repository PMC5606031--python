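"""ODM parsing, serialization, referential integrity, and value validation."""

import datetime
import random
import re
from decimal import Decimal, InvalidOperation

import pytest

from odmfhir import (
    DanglingOidError,
    OdmParseError,
    OdmStructureError,
    OdmVocabularyError,
    read_odm,
    validate_item_value,
    validate_referential_integrity,
    write_odm,
)
from odmfhir.odm import CodeList, CodeListItem, ItemDef, RangeCheck

from conftest import small_study

MINIMAL = """<?xml version="1.0" encoding="UTF-8"?>
<ODM xmlns="http://www.cdisc.org/ns/odm/v1.3" FileOID="f" FileType="Snapshot"
     CreationDateTime="2016-01-01T00:00:00" ODMVersion="1.3.2">
  <Study OID="ST.1">
    <GlobalVariables><StudyName>Min</StudyName><ProtocolName>P</ProtocolName></GlobalVariables>
    <MetaDataVersion OID="MDV.1" Name="M">
      <ItemDef OID="IT.1" Name="Item" DataType="{datatype}"/>
    </MetaDataVersion>
  </Study>
</ODM>
"""


class TestReadOdm:
    def test_worked_example_structure(self, bp):
        study, _ = bp
        xml = write_odm(study)
        parsed = read_odm(xml)
        assert len(parsed.subjects) == 1
        subj = parsed.subjects[0]
        assert len(subj.events) == 1
        assert len(subj.events[0].forms) == 1
        values = {
            i.item_oid: i.value
            for i in subj.events[0].forms[0].item_groups[0].items
        }
        assert values["IT.SYSBP"] == "119"
        assert values["IT.DIABP"] == "79"

    def test_metadata_only_document_has_empty_clinical_data(self):
        study = read_odm(MINIMAL.format(datatype="integer"))
        assert study.subjects == []
        assert "IT.1" in study.metadata.item_defs

    def test_malformed_xml_reports_line(self):
        with pytest.raises(OdmParseError) as err:
            read_odm("<ODM>\n<broken\n")
        assert err.value.line is not None

    def test_missing_study_is_structural_error(self):
        xml = '<ODM xmlns="http://www.cdisc.org/ns/odm/v1.3"/>'
        with pytest.raises(OdmStructureError, match="Study"):
            read_odm(xml)

    def test_foreign_namespace_rejected(self):
        xml = '<ODM xmlns="http://www.cdisc.org/ns/odm/v2.0"><Study OID="x"/></ODM>'
        with pytest.raises(OdmStructureError, match="namespace"):
            read_odm(xml)

    def test_unknown_datatype_names_the_item(self):
        with pytest.raises(OdmVocabularyError, match="IT.1"):
            read_odm(MINIMAL.format(datatype="hexFloat"))

    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_identity(self, seed):
        """read(write(study)) is the identity, structurally, across seeds."""
        study, _ = small_study(seed)
        assert read_odm(write_odm(study)) == study

    def test_write_read_write_is_byte_idempotent(self):
        study, _ = small_study(7)
        once = write_odm(study)
        again = write_odm(read_odm(once))
        assert once == again

    def test_opaque_extension_preserved_and_round_trips(self):
        xml = MINIMAL.format(datatype="integer").replace(
            '<ItemDef OID="IT.1" Name="Item" DataType="integer"/>',
            '<ItemDef OID="IT.1" Name="Item" DataType="integer">'
            '<Alias xmlns="http://www.cdisc.org/ns/odm/v1.3" Context="x" Name="y"/>'
            "</ItemDef>",
        )
        study = read_odm(xml)
        assert len(study.metadata.item_defs["IT.1"].extras) == 1
        assert read_odm(write_odm(study)) == study


class TestWriteOdm:
    def test_minimal_study_elements(self):
        study = read_odm(MINIMAL.format(datatype="integer"))
        xml = write_odm(study)
        assert xml.count("<Study ") == 1
        assert xml.count("<MetaDataVersion ") == 1

    def test_subject_count_preserved(self):
        study, _ = small_study(3)
        assert len(study.subjects) == 2
        xml = write_odm(study)
        assert xml.count("<SubjectData ") == 2

    def test_refuses_dangling_oid(self):
        study, _ = small_study(1)
        study.subjects[0].events[0].study_event_oid = "SE.GONE"
        with pytest.raises(DanglingOidError, match="SE.GONE"):
            write_odm(study)


class TestReferentialIntegrity:
    def test_intact_study_has_no_violations(self):
        study, _ = small_study(11)
        assert validate_referential_integrity(study) == []

    def test_deleted_item_def_yields_exactly_matching_violations(self):
        """Brute-force oracle: removing one ItemDef must flag precisely the
        leaves (and metadata refs) naming that OID, nothing else."""
        study, _ = small_study(5)
        victim = next(iter(study.metadata.item_defs))
        expected_leaves = sum(
            1 for _path, _s, _e, _f, _g, item in study.iter_leaves()
            if item.item_oid == victim
        )
        expected_refs = sum(
            1 for igd in study.metadata.item_group_defs.values()
            for ref in igd.item_refs if ref == victim
        )
        del study.metadata.item_defs[victim]
        violations = validate_referential_integrity(study)
        assert len(violations) == expected_leaves + expected_refs
        assert all(victim in v.message for v in violations)

    def test_unknown_event_oid_yields_one_violation_at_path(self):
        study, _ = small_study(2)
        study.subjects[0].events[0].study_event_oid = "SE.UNKNOWN"
        violations = [
            v for v in validate_referential_integrity(study)
            if "SE.UNKNOWN" in v.message
        ]
        assert len(violations) == 1
        assert "subject[S001]" in violations[0].path


# ---------------------------------------------------------------------------
# Independent re-implementation of the value-check table (oracle)
# ---------------------------------------------------------------------------


def oracle_check(item_def: ItemDef, raw: str, code_lists) -> tuple[bool, int]:
    """(parsed_ok, number_of_violations) computed independently."""
    dt = item_def.datatype
    parsed = None
    if dt == "integer":
        if re.fullmatch(r"[+-]?\d+", raw.strip()):
            parsed = int(raw)
    elif dt == "float":
        try:
            parsed = Decimal(raw.strip())
        except InvalidOperation:
            parsed = None
    elif dt == "date":
        try:
            parsed = datetime.date.fromisoformat(raw.strip())
        except ValueError:
            parsed = None
    elif dt == "time":
        try:
            parsed = datetime.time.fromisoformat(raw.strip())
        except ValueError:
            parsed = None
    elif dt == "datetime":
        try:
            parsed = datetime.datetime.fromisoformat(raw.strip())
        except ValueError:
            parsed = None
    elif dt == "boolean":
        parsed = raw.strip().lower() if raw.strip().lower() in ("true", "false", "0", "1") else None
    else:
        parsed = raw
    if parsed is None:
        return False, 1

    n = 0
    if item_def.length is not None:
        if dt == "integer":
            measured = len(str(abs(int(raw))))
        elif dt == "float":
            measured = sum(ch.isdigit() for ch in raw)
        else:
            measured = len(raw)
        n += measured > item_def.length
    if item_def.significant_digits is not None and dt == "float":
        frac = raw.strip().split(".", 1)
        decimals = len(frac[1]) if len(frac) == 2 else 0
        # exponent forms are not generated below
        n += decimals > item_def.significant_digits
    if dt in ("integer", "float"):
        v = Decimal(raw.strip())
        for rc in item_def.range_checks:
            ok = {
                "LT": v < rc.bound, "LE": v <= rc.bound, "GT": v > rc.bound,
                "GE": v >= rc.bound, "EQ": v == rc.bound, "NE": v != rc.bound,
            }[rc.comparator]
            n += not ok
    if item_def.code_list_oid is not None:
        cl = code_lists.get(item_def.code_list_oid)
        n += cl is None or raw not in [i.coded_value for i in cl.items]
    return True, n


def _random_item_def(rng: random.Random) -> tuple[ItemDef, dict]:
    dt = rng.choice(["text", "integer", "float", "date", "time", "datetime", "boolean"])
    kwargs = {"oid": "IT.R", "name": "r", "datatype": dt}
    code_lists = {}
    if dt in ("integer", "float") and rng.random() < 0.6:
        kwargs["range_checks"] = [
            RangeCheck(comparator=rng.choice(["LT", "LE", "GT", "GE", "EQ", "NE"]),
                       bound=Decimal(rng.randint(-50, 150))),
        ]
    if dt == "float" and rng.random() < 0.5:
        kwargs["significant_digits"] = rng.randint(0, 3)
    if rng.random() < 0.4:
        kwargs["length"] = rng.randint(1, 8)
    if dt == "text" and rng.random() < 0.4:
        kwargs["code_list_oid"] = "CL.R"
        code_lists["CL.R"] = CodeList(
            oid="CL.R", name="r",
            items=[CodeListItem(coded_value=c) for c in ("A", "B", "C")],
        )
    return ItemDef(**kwargs), code_lists


def _random_raw(rng: random.Random, dt: str) -> str:
    pools = {
        "integer": ["0", "42", "-5", "119", "007", "4.2", "x", ""],
        "float": ["0", "3.14", "-2.5", "100.123", "nope", "1e3", ""],
        "text": ["A", "B", "Z", "hello world", ""],
        "date": ["2016-03-01", "2016-13-01", "yesterday", ""],
        "time": ["10:00:00", "25:00", "noon", ""],
        "datetime": ["2016-03-01T10:00:00", "2016-03-01", "soon", ""],
        "boolean": ["true", "false", "1", "0", "yes", ""],
    }
    return rng.choice(pools[dt])


class TestValidateItemValue:
    def test_integer_passthrough(self, bp):
        study, _ = bp
        check = validate_item_value(study.metadata.item_defs["IT.SYSBP"], "119")
        assert check.ok and check.value == 119

    def test_range_check_violation_cites_comparator_and_bound(self):
        idf = ItemDef(oid="IT.X", name="x", datatype="integer",
                      range_checks=[RangeCheck(comparator="GE", bound=0)])
        check = validate_item_value(idf, "-5")
        assert not check.ok
        assert "GE 0" in check.violations[0].message

    def test_agrees_with_independent_oracle_on_random_pairs(self):
        rng = random.Random(20160919)
        for _ in range(1000):
            idf, code_lists = _random_item_def(rng)
            raw = _random_raw(rng, idf.datatype)
            expect_parsed, expect_n = oracle_check(idf, raw, code_lists)
            check = validate_item_value(idf, raw, code_lists)
            assert (check.value is not None) == expect_parsed, (idf, raw)
            assert len(check.violations) == expect_n, (idf, raw, check.violations)
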