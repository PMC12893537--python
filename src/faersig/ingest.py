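"""Reading and writing FAERS-style quarterly ASCII tables.

The dialect is dollar-sign-delimited text with one header line per file.
Five tables make up a quarter: DEMO (one row per report version), DRUG
(one row per drug mention), REAC (one row per reported PT), OUTC (one row
per outcome code), THER (one row per therapy episode). Rows are joined
into report records on ``primaryid``; each FAERS case may appear as
several versions (distinct ``primaryid``, shared ``caseid``), resolved by
:func:`deduplicate`.

The reader is deliberately strict: a data line whose field count differs
from the header is rejected and counted in the quality log, never
silently NaN-filled.
"""
from __future__ import annotations

import datetime
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, DataFormatError
from .records import (
    DrugEntry,
    ParsedDate,
    QualityLog,
    ReportRecord,
    assign_age_group,
)
from .vocab import DrugDictionary

DELIMITER = "$"

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER")

#: Minimal column sets per table; files may carry extra columns.
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
    ),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "route"),
    "REAC": ("primaryid", "caseid", "pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
}

# FAERS age unit codes -> factor converting the stored value to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 130.0

SEX_MAP = {"F": "female", "M": "male"}

OCCP_MAP = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "LW": "Lawyer",
    "RN": "Registered Nurse",
}

ROUTE_MAP = {
    "SUBCUTANEOUS": "subcutaneous",
    "SC": "subcutaneous",
    "INTRAVENOUS": "intravenous",
    "IV": "intravenous",
    "INTRAVENOUS (NOT OTHERWISE SPECIFIED)": "intravenous",
    "ORAL": "oral",
    "PO": "oral",
    "TRANSPLACENTAL": "transplacental",
    "INTRAMUSCULAR": "intramuscular",
    "IM": "intramuscular",
}

OUTC_MAP = {
    "HO": "hospitalization",
    "OT": "other_serious",
    "DE": "death",
    "LT": "life_threatening",
    "DS": "disability",
    "RI": "required_intervention",
    "CA": "congenital_anomaly",
}


@dataclass(frozen=True)
class RawRow:
    """One data line of an ASCII table, untrimmed."""

    table_name: str
    fields: dict[str, str]


def parse_faers_date(text: str) -> Optional[ParsedDate]:
    """Parse an 8/6/4-digit FAERS date; partial dates are padded with 01.

    Returns None for empty or unparseable values.
    """
    t = text.strip()
    if not t or not t.isdigit():
        return None
    try:
        if len(t) == 8:
            return ParsedDate(datetime.date(int(t[:4]), int(t[4:6]), int(t[6:8])), "day")
        if len(t) == 6:
            return ParsedDate(datetime.date(int(t[:4]), int(t[4:6]), 1), "month")
        if len(t) == 4:
            return ParsedDate(datetime.date(int(t), 1, 1), "year")
    except ValueError:
        return None
    return None


def table_name_from_path(path: Path) -> str:
    stem = path.name.upper()
    for name in TABLE_NAMES:
        if stem.startswith(name):
            return name
    raise ConfigError(f"cannot infer table name from file name: {path.name}")


def read_ascii_table(
    path: Path, schemas: Mapping[str, tuple[str, ...]] = TABLE_SCHEMAS
) -> tuple[str, list[RawRow], int]:
    """Read one dollar-delimited table file.

    Returns (table name, rows, malformed-line count). A line whose field
    count differs from the header's is rejected and counted.
    """
    path = Path(path)
    name = table_name_from_path(path)
    if name not in schemas:
        raise ConfigError(f"unknown table name {name!r} for file {path.name}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise DataFormatError(f"missing header line in {path}")
    header = lines[0].split(DELIMITER)
    missing = [c for c in schemas[name] if c not in header]
    if missing:
        raise DataFormatError(f"{path}: header lacks required columns {missing}")
    rows: list[RawRow] = []
    malformed = 0
    for line in lines[1:]:
        if line == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) != len(header):
            malformed += 1
            continue
        rows.append(RawRow(name, dict(zip(header, parts))))
    return name, rows, malformed


def parse_tables(
    paths: Sequence[Path | str],
    schemas: Mapping[str, tuple[str, ...]] = TABLE_SCHEMAS,
) -> tuple[dict[str, list[RawRow]], QualityLog]:
    """Read several table files, concatenating rows per table name."""
    tables: dict[str, list[RawRow]] = {name: [] for name in TABLE_NAMES}
    qlog = QualityLog()
    for p in paths:
        name, rows, malformed = read_ascii_table(Path(p), schemas)
        tables[name].extend(rows)
        qlog.malformed_lines += malformed
    return tables, qlog


def normalize_demographics(record: ReportRecord, raw: Mapping[str, str]) -> QualityLog:
    """Fill demographic fields of a report draft from its DEMO row.

    Total: every enum field ends up populated (possibly unknown/other).
    Implausible ages (negative or > 130 years) become missing and are
    counted in the returned quality log.
    """
    qlog = QualityLog()
    record.sex = SEX_MAP.get(raw.get("sex", "").strip().upper(), "unknown")
    record.reporter_type = OCCP_MAP.get(raw.get("occp_cod", "").strip().upper(), "unknown")
    country = raw.get("reporter_country", "").strip()
    record.country = country if country else "unknown"

    age_txt = raw.get("age", "").strip()
    unit = raw.get("age_cod", "").strip().upper()
    age_years: Optional[float] = None
    if age_txt:
        try:
            value = float(age_txt)
        except ValueError:
            value = None
        if value is not None and unit in AGE_UNIT_TO_YEARS:
            age_years = value * AGE_UNIT_TO_YEARS[unit]
        elif value is not None and not unit:
            age_years = value  # bare ages are taken as years
        if age_years is not None and not (0.0 <= age_years <= MAX_PLAUSIBLE_AGE):
            qlog.implausible_ages += 1
            age_years = None
    record.age_years = age_years
    record.age_group = assign_age_group(age_years)

    record.report_date = parse_faers_date(raw.get("fda_dt", ""))
    record.event_onset = parse_faers_date(raw.get("event_dt", ""))
    for d in (record.report_date, record.event_onset):
        if d is not None and not d.full:
            qlog.partial_dates += 1
    return qlog


def assemble_reports(
    tables: Mapping[str, list[RawRow]], drug_dict: DrugDictionary
) -> tuple[list[ReportRecord], QualityLog]:
    """Join raw rows into report records on primaryid.

    Reports with no REAC rows are dropped (events must be non-empty) and
    counted in the quality log. Route is taken from the first
    primary-suspect drug entry; therapy start from the THER row matching
    that drug's sequence number.
    """
    qlog = QualityLog()
    drug_rows: dict[str, list[RawRow]] = defaultdict(list)
    reac_rows: dict[str, list[RawRow]] = defaultdict(list)
    outc_rows: dict[str, list[RawRow]] = defaultdict(list)
    ther_rows: dict[str, list[RawRow]] = defaultdict(list)
    for row in tables.get("DRUG", []):
        drug_rows[row.fields["primaryid"]].append(row)
    for row in tables.get("REAC", []):
        reac_rows[row.fields["primaryid"]].append(row)
    for row in tables.get("OUTC", []):
        outc_rows[row.fields["primaryid"]].append(row)
    for row in tables.get("THER", []):
        ther_rows[row.fields["primaryid"]].append(row)

    records: list[ReportRecord] = []
    for demo in tables.get("DEMO", []):
        pid = demo.fields["primaryid"]
        events = frozenset(
            r.fields["pt"].strip().lower() for r in reac_rows.get(pid, []) if r.fields["pt"].strip()
        )
        if not events:
            qlog.eventless_reports += 1
            continue
        record = ReportRecord(primary_id=pid, case_id=demo.fields["caseid"].strip())
        qlog = qlog.merge(normalize_demographics(record, demo.fields))
        record.events = events

        drugs: list[DrugEntry] = []
        ps_seq: Optional[str] = None
        ps_route = ""
        for row in drug_rows.get(pid, []):
            raw_name = row.fields["drugname"]
            standard, _cls = drug_dict.classify(raw_name)
            role = row.fields.get("role_cod", "").strip().upper()
            entry = DrugEntry(name_raw=raw_name, name_standard=standard, role=role)
            drugs.append(entry)
            if entry.role == "PS" and ps_seq is None:
                ps_seq = row.fields.get("drug_seq", "").strip()
                ps_route = row.fields.get("route", "")
        record.drugs = drugs
        record.route = ROUTE_MAP.get(ps_route.strip().upper(), "other")

        record.outcomes = frozenset(
            OUTC_MAP[code]
            for code in (
                r.fields["outc_cod"].strip().upper() for r in outc_rows.get(pid, [])
            )
            if code in OUTC_MAP
        )

        if ps_seq is not None:
            for row in ther_rows.get(pid, []):
                if row.fields.get("dsg_drug_seq", "").strip() == ps_seq:
                    record.therapy_start = parse_faers_date(row.fields.get("start_dt", ""))
                    if record.therapy_start is not None and not record.therapy_start.full:
                        qlog.partial_dates += 1
                    break
        records.append(record)
    return records, qlog


def load_reports(
    paths: Sequence[Path | str], drug_dict: DrugDictionary
) -> tuple[list[ReportRecord], QualityLog]:
    """Parse ASCII files and assemble normalized report drafts."""
    tables, qlog = parse_tables(paths)
    records, qlog2 = assemble_reports(tables, drug_dict)
    return records, qlog.merge(qlog2)


def _pid_sort_key(pid: str):
    # numeric ids compare numerically (FAERS issues increasing integers)
    return (0, int(pid), "") if pid.isdigit() else (1, 0, pid)


def deduplicate(reports: Iterable[ReportRecord]) -> list[ReportRecord]:
    """Keep the most recent version of each case.

    Survivor per case_id = maximum report_date (missing dates sort
    earliest), ties broken by maximum primary_id. Output sorted by
    case_id for determinism. Idempotent.
    """
    by_case: dict[str, ReportRecord] = {}
    for rec in reports:
        cur = by_case.get(rec.case_id)
        if cur is None:
            by_case[rec.case_id] = rec
            continue
        key_new = (
            rec.report_date.date if rec.report_date else datetime.date.min,
            _pid_sort_key(rec.primary_id),
        )
        key_cur = (
            cur.report_date.date if cur.report_date else datetime.date.min,
            _pid_sort_key(cur.primary_id),
        )
        if key_new > key_cur:
            by_case[rec.case_id] = rec
    return [by_case[c] for c in sorted(by_case)]


def select_primary_suspect(
    reports: Iterable[ReportRecord], drug: str
) -> list[ReportRecord]:
    """Reports where `drug` (standardized name) appears with role PS."""
    return [r for r in reports if r.has_drug(drug, role="PS")]


# ---------------------------------------------------------------------------
# Writer (round-trip counterpart of the reader; used by the synthetic module)
# ---------------------------------------------------------------------------

def _date_to_text(d: Optional[ParsedDate]) -> str:
    if d is None:
        return ""
    if d.precision == "day":
        return d.date.strftime("%Y%m%d")
    if d.precision == "month":
        return d.date.strftime("%Y%m")
    return d.date.strftime("%Y")


_INV_SEX = {"female": "F", "male": "M", "unknown": ""}
_INV_OCCP = {v: k for k, v in OCCP_MAP.items()}
_INV_ROUTE = {
    "subcutaneous": "SUBCUTANEOUS",
    "intravenous": "INTRAVENOUS",
    "oral": "ORAL",
    "transplacental": "TRANSPLACENTAL",
    "intramuscular": "INTRAMUSCULAR",
    "other": "",
}
_INV_OUTC = {v: k for k, v in OUTC_MAP.items()}


def records_to_tables(records: Sequence[ReportRecord]) -> dict[str, pd.DataFrame]:
    """Serialize report records back to the five-table layout."""
    demo, drug, reac, outc, ther = [], [], [], [], []
    for rec in records:
        demo.append(
            {
                "primaryid": rec.primary_id,
                "caseid": rec.case_id,
                "fda_dt": _date_to_text(rec.report_date),
                "event_dt": _date_to_text(rec.event_onset),
                "age": "" if rec.age_years is None else repr(float(rec.age_years)),
                "age_cod": "" if rec.age_years is None else "YR",
                "sex": _INV_SEX.get(rec.sex, ""),
                "occp_cod": _INV_OCCP.get(rec.reporter_type, ""),
                "reporter_country": "" if rec.country == "unknown" else rec.country,
            }
        )
        ps_seq = None
        for i, entry in enumerate(rec.drugs, start=1):
            route = ""
            if entry.role == "PS" and ps_seq is None:
                ps_seq = i
                route = _INV_ROUTE.get(rec.route, "")
            drug.append(
                {
                    "primaryid": rec.primary_id,
                    "caseid": rec.case_id,
                    "drug_seq": str(i),
                    "role_cod": entry.role,
                    "drugname": entry.name_raw,
                    "route": route,
                }
            )
        for pt in sorted(rec.events):
            reac.append({"primaryid": rec.primary_id, "caseid": rec.case_id, "pt": pt})
        for oc in sorted(rec.outcomes):
            outc.append(
                {"primaryid": rec.primary_id, "caseid": rec.case_id, "outc_cod": _INV_OUTC[oc]}
            )
        if rec.therapy_start is not None and ps_seq is not None:
            ther.append(
                {
                    "primaryid": rec.primary_id,
                    "caseid": rec.case_id,
                    "dsg_drug_seq": str(ps_seq),
                    "start_dt": _date_to_text(rec.therapy_start),
                    "end_dt": "",
                }
            )
    frames = {
        "DEMO": pd.DataFrame(demo, columns=list(TABLE_SCHEMAS["DEMO"])),
        "DRUG": pd.DataFrame(drug, columns=list(TABLE_SCHEMAS["DRUG"])),
        "REAC": pd.DataFrame(reac, columns=list(TABLE_SCHEMAS["REAC"])),
        "OUTC": pd.DataFrame(outc, columns=list(TABLE_SCHEMAS["OUTC"])),
        "THER": pd.DataFrame(ther, columns=list(TABLE_SCHEMAS["THER"])),
    }
    return frames


def write_tables(
    frames: Mapping[str, pd.DataFrame], outdir: Path | str, quarter: str = "24Q1"
) -> list[Path]:
    """Write table frames as dollar-delimited ASCII files (DEMOyyQq etc.)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in TABLE_NAMES:
        if name not in frames:
            continue
        path = outdir / f"{name}{quarter}.txt"
        frames[name].to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")
        paths.append(path)
    return paths
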