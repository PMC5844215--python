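"""Record assembly, sorting, and table round-trips."""

import io
import json
import random

import pytest

from snpminer import (
    AbstractRecord,
    CohortInfo,
    assemble_records,
    extract_associations,
    read_table,
    sort_records,
    write_table,
)
from snpminer.examples import example_sentence
from snpminer.nlp import analyze
from snpminer.report import AssociationRecord


def rec(rsid="rs1", pmid="10", **kw):
    kw.setdefault("evidence_sentence", f"{rsid} evidence")
    return AssociationRecord(rsid=rsid, pmid=pmid, **kw)


@pytest.fixture
def sample_records():
    return [
        rec("rs2736100", p_value=1.0e-27),
        rec("rs4488809", p_value=7.2e-26),
        rec("rs99", p_value=None),                 # missing key
        rec("rs753955", p_value=1.5e-12, or_value=1.1),
    ]


class TestAssemble:
    def test_cohort_copied_to_every_row(self):
        record = AbstractRecord(pmid="26141218", abstract=example_sentence("23143601"))
        pairs = extract_associations(record.pmid, analyze(record.abstract))
        cohort = CohortInfo(patient_size=889, control_size=1005)
        rows = assemble_records(record, pairs, cohort)
        assert len(rows) == 3
        assert all((r.patient_size, r.control_size) == (889, 1005) for r in rows)

    def test_no_pairs(self):
        record = AbstractRecord(pmid="1", abstract="x")
        assert assemble_records(record, [], CohortInfo()) == []

    def test_pair_without_or_leaves_field_absent(self):
        record = AbstractRecord(pmid="21552555", abstract=example_sentence("21552555"))
        pairs = extract_associations(record.pmid, analyze(record.abstract))
        (row,) = assemble_records(record, pairs, CohortInfo())
        assert row.or_value is None and row.p_value == 2.67e-9


class TestSort:
    def test_ascending_p_puts_strongest_first(self, sample_records):
        ordered = sort_records(sample_records, "p_value")
        assert ordered[0].rsid == "rs2736100"

    def test_missing_values_last_both_directions(self, sample_records):
        for ascending in (True, False):
            ordered = sort_records(sample_records, "p_value", ascending)
            assert ordered[-1].rsid == "rs99"

    def test_rsid_sorts_numerically(self):
        records = [rec("rs100"), rec("rs20"), rec("rs3")]
        assert [r.rsid for r in sort_records(records, "rsid")] == [
            "rs3", "rs20", "rs100",
        ]

    def test_single_record_unchanged(self):
        records = [rec()]
        assert sort_records(records, "or_value") == records

    def test_unknown_key(self):
        with pytest.raises(ValueError, match="unknown sort key"):
            sort_records([], "significance")

    def test_agrees_with_comparison_oracle_and_permutes(self):
        rng = random.Random(5)
        records = [
            rec(f"rs{i}", p_value=rng.choice([None, rng.random()]))
            for i in range(40)
        ]
        ordered = sort_records(records, "p_value")
        assert sorted(map(id, ordered)) == sorted(map(id, records))
        oracle = sorted(
            (r for r in records if r.p_value is not None), key=lambda r: r.p_value
        ) + [r for r in records if r.p_value is None]
        assert ordered == oracle


class TestTables:
    def test_header_plus_one_line(self, sample_records):
        buf = io.StringIO()
        write_table(sample_records[:1], "tsv", buf)
        lines = buf.getvalue().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t")[0] == "rsid"

    def test_float_rendering(self):
        buf = io.StringIO()
        write_table([rec(p_value=3.54e-18)], "tsv", buf)
        assert "3.540000e-18" in buf.getvalue()

    @pytest.mark.parametrize("fmt", ["tsv", "csv"])
    def test_write_read_roundtrip(self, fmt, sample_records):
        full = [
            rec("rs5770917", pmid="18820697", p_value=4.4e-7, or_value=1.79,
                patient_size=889, control_size=1005, ethnicity="Japanese",
                pub_date="2008-09-26"),
            *sample_records,
        ]
        buf = io.StringIO()
        write_table(full, fmt, buf)
        buf.seek(0)
        again = read_table(buf, fmt)
        assert len(again) == len(full)
        for a, b in zip(again, full):
            assert a.rsid == b.rsid and a.pmid == b.pmid
            assert a.evidence_sentence == b.evidence_sentence
            assert a.ethnicity == b.ethnicity and a.pub_date == b.pub_date
            assert a.patient_size == b.patient_size
            for x, y in ((a.p_value, b.p_value), (a.or_value, b.or_value)):
                if y is None:
                    assert x is None
                else:
                    assert abs(x - y) <= abs(y) * 1e-6

    def test_json_omits_absent_keys(self):
        buf = io.StringIO()
        write_table([rec(p_value=0.03)], "json", buf)
        (obj,) = json.loads(buf.getvalue())
        assert "or_value" not in obj and obj["p_value"] == 0.03

    def test_unwritable_destination_surfaces_path(self, tmp_path):
        with pytest.raises(OSError, match="no/such"):
            write_table([], "tsv", tmp_path / "no" / "such" / "file.tsv")
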