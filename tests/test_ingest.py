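"""Reader, deduplication, primary-suspect filter and demographic coding."""
from __future__ import annotations

import pytest

from faersig import ingest
from faersig.errors import ConfigError, DataFormatError
from faersig.ingest import (
    deduplicate,
    load_reports,
    normalize_demographics,
    parse_tables,
    read_ascii_table,
    records_to_tables,
    select_primary_suspect,
    write_tables,
)
from faersig.records import ReportRecord
from faersig.synthetic import default_config, generate

from conftest import make_report


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


DEMO_HEADER = "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod$reporter_country"


class TestReader:
    def test_header_plus_two_rows(self, tmp_path):
        p = write(
            tmp_path / "DEMO24Q1.txt",
            DEMO_HEADER + "\n"
            "11$1$20200101$20200101$65$YR$F$MD$US\n"
            "12$2$20200202$$30$YR$M$CN$FR\n",
        )
        name, rows, malformed = read_ascii_table(p)
        assert name == "DEMO" and malformed == 0
        assert len(rows) == 2
        assert list(rows[0].fields) == DEMO_HEADER.split("$")
        assert rows[1].fields["sex"] == "M"

    def test_short_row_rejected_and_counted(self, tmp_path):
        p = write(
            tmp_path / "DRUG24Q1.txt",
            "primaryid$caseid$drug_seq$role_cod$drugname$route\n"
            "11$1$1$PS$fondaparinux\n"  # one field short
            "12$2$1$PS$fondaparinux$SUBCUTANEOUS\n",
        )
        _, rows, malformed = read_ascii_table(p)
        assert len(rows) == 1 and malformed == 1

    def test_missing_header_is_format_error(self, tmp_path):
        p = write(tmp_path / "REAC24Q1.txt", "")
        with pytest.raises(DataFormatError):
            read_ascii_table(p)

    def test_unknown_table_name_is_config_error(self, tmp_path):
        p = write(tmp_path / "BOGUS24Q1.txt", "a$b\n1$2\n")
        with pytest.raises(ConfigError):
            read_ascii_table(p)

    def test_fixture_quarter_joins_rows_into_drafts(self, tmp_path, drug_dict):
        # 5 reports; drug counts 2,1,2,2,1 and event counts 2,1,1,2,1 by hand
        write(
            tmp_path / "DEMO24Q1.txt",
            DEMO_HEADER + "\n" + "\n".join(
                f"{i}1${i}$20200101$$65$YR$F$MD$US" for i in range(1, 6)
            ) + "\n",
        )
        drug_lines = [
            "11$1$1$PS$fondaparinux$SC", "11$1$2$C$warfarin$",
            "21$2$1$PS$enoxaparin$SC",
            "31$3$1$PS$fondaparinux$SC", "31$3$2$SS$aspirin$",
            "41$4$1$PS$heparin$IV", "41$4$2$C$aspirin$",
            "51$5$1$PS$fondaparinux$SC",
        ]
        write(
            tmp_path / "DRUG24Q1.txt",
            "primaryid$caseid$drug_seq$role_cod$drugname$route\n" + "\n".join(drug_lines) + "\n",
        )
        reac_lines = [
            "11$1$haematoma", "11$1$anaemia",
            "21$2$haemorrhage",
            "31$3$haematoma",
            "41$4$epistaxis", "41$4$haematoma",
            "51$5$rash",
        ]
        write(
            tmp_path / "REAC24Q1.txt",
            "primaryid$caseid$pt\n" + "\n".join(reac_lines) + "\n",
        )
        records, qlog = load_reports(sorted(tmp_path.glob("*.txt")), drug_dict)
        assert len(records) == 5
        by_pid = {r.primary_id: r for r in records}
        assert [len(by_pid[f"{i}1"].drugs) for i in range(1, 6)] == [2, 1, 2, 2, 1]
        assert [len(by_pid[f"{i}1"].events) for i in range(1, 6)] == [2, 1, 1, 2, 1]
        assert qlog.malformed_lines == 0


class TestDeduplicate:
    def test_most_recent_version_survives(self):
        recs = [
            make_report("100", case="7", date="20200101"),
            make_report("101", case="7", date="20200301"),
        ]
        out = deduplicate(recs)
        assert [r.primary_id for r in out] == ["101"]

    def test_idempotent(self, small_synthetic):
        _, records = small_synthetic
        once = deduplicate(records)
        assert deduplicate(once) == once

    def test_tie_on_date_broken_by_larger_primary_id(self):
        recs = [
            make_report("100", case="7", date="20200101"),
            make_report("200", case="7", date="20200101"),
        ]
        assert [r.primary_id for r in deduplicate(recs)] == ["200"]

    def test_case_partition_conserved(self, small_synthetic):
        _, records = small_synthetic
        out = deduplicate(records)
        assert len(out) == len({r.case_id for r in records})
        assert [r.case_id for r in out] == sorted(r.case_id for r in out)


class TestPrimarySuspectFilter:
    def test_ss_only_excluded_ps_included(self):
        recs = [
            make_report("1", drugs=[("fondaparinux", "SS")]),
            make_report(
                "2",
                drugs=[("fondaparinux", "PS")] + [(f"d{i}", "C") for i in range(5)],
            ),
        ]
        out = select_primary_suspect(recs, "fondaparinux")
        assert [r.primary_id for r in out] == ["2"]

    def test_hand_enumerated_count(self):
        recs = [
            make_report(str(i), drugs=[("fondaparinux", "PS" if i % 3 == 0 else "C")])
            for i in range(1, 11)
        ]
        expected = [r for r in recs if any(d.role == "PS" for d in r.drugs)]
        assert select_primary_suspect(recs, "fondaparinux") == expected
        assert len(expected) == 3  # 3, 6, 9


class TestNormalizeDemographics:
    @pytest.mark.parametrize(
        "value,unit,years,group",
        [
            ("65", "YR", 65.0, ">=65"),
            ("7.5", "DEC", 75.0, ">=65"),
            ("18", "MON", 1.5, "<18"),
            ("52", "WK", 1.0, "<18"),
            ("64.99", "YR", 64.99, "18-65"),
        ],
    )
    def test_age_unit_conversion(self, value, unit, years, group):
        rec = ReportRecord(primary_id="1", case_id="1")
        normalize_demographics(rec, {"age": value, "age_cod": unit})
        assert rec.age_years == pytest.approx(years)
        assert rec.age_group == group

    def test_implausible_age_becomes_missing_and_logged(self):
        rec = ReportRecord(primary_id="1", case_id="1")
        qlog = normalize_demographics(rec, {"age": "250", "age_cod": "YR"})
        assert rec.age_years is None and rec.age_group == "unknown"
        assert qlog.implausible_ages == 1

    def test_total_on_garbage_input(self):
        rec = ReportRecord(primary_id="1", case_id="1")
        normalize_demographics(
            rec, {"age": "abc", "age_cod": "??", "sex": "X", "occp_cod": "ZZ"}
        )
        assert rec.sex == "unknown"
        assert rec.reporter_type == "unknown"
        assert rec.age_group == "unknown"
        assert rec.country == "unknown"


def test_ascii_round_trip_field_for_field(tmp_path, drug_dict):
    """Write -> parse reproduces the deduplicated record set exactly."""
    cfg = default_config(n_reports=120, seed=9)
    records = deduplicate(generate(cfg))
    write_tables(records_to_tables(records), tmp_path)
    reparsed, _ = load_reports(sorted(tmp_path.glob("*.txt")), drug_dict)
    assert deduplicate(reparsed) == records


def test_partial_dates_order_dedup_but_are_flagged(tmp_path):
    _, rows, _ = read_ascii_table(
        write(
            tmp_path / "DEMO24Q1.txt",
            DEMO_HEADER + "\n11$1$202003$$$$$$\n",
        )
    )
    assert ingest.parse_faers_date(rows[0].fields["fda_dt"]).precision == "month"
    assert ingest.parse_faers_date("20200115").full
    assert ingest.parse_faers_date("") is None
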