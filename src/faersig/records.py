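"""Core record types shared across the pipeline.

A :class:`ReportRecord` is one spontaneous safety report after ingestion:
case identity and version, demographics, the drug list with role codes,
the set of reported event preferred terms (PTs), and the dates needed for
deduplication and time-to-onset analysis.
"""
from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Optional

# FAERS role codes: primary suspect, secondary suspect, concomitant, interacting
ROLE_CODES = ("PS", "SS", "C", "I")

SEX_LEVELS = ("female", "male", "unknown")
AGE_GROUPS = ("<18", "18-65", ">=65", "unknown")
REPORTER_TYPES = (
    "Consumer",
    "Physician",
    "Pharmacist",
    "Other health-professional",
    "Lawyer",
    "Registered Nurse",
    "unknown",
)
ROUTES = (
    "subcutaneous",
    "intravenous",
    "oral",
    "transplacental",
    "intramuscular",
    "other",
)
OUTCOMES = (
    "hospitalization",
    "other_serious",
    "death",
    "life_threatening",
    "disability",
    "required_intervention",
    "congenital_anomaly",
)


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    name_raw: str
    name_standard: str
    role: str = "C"  # unrecognized role codes collapse to concomitant

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            object.__setattr__(self, "role", "C")


@dataclass(frozen=True)
class ParsedDate:
    """A FAERS 8-digit date, possibly partial.

    Partial dates (missing day and/or month) are padded with 01 so they
    still order reports for deduplication, but they are flagged so that
    day-resolution arithmetic (time to onset) treats them as missing.
    """

    date: datetime.date
    precision: str  # "day" | "month" | "year"

    @property
    def full(self) -> bool:
        return self.precision == "day"


@dataclass
class ReportRecord:
    """One deduplicated safety report."""

    primary_id: str
    case_id: str
    report_date: Optional[ParsedDate] = None
    sex: str = "unknown"
    age_years: Optional[float] = None
    age_group: str = "unknown"
    reporter_type: str = "unknown"
    country: str = "unknown"
    route: str = "other"
    outcomes: frozenset[str] = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    events: frozenset[str] = frozenset()
    therapy_start: Optional[ParsedDate] = None
    event_onset: Optional[ParsedDate] = None

    def has_drug(self, name_standard: str, role: Optional[str] = None) -> bool:
        return any(
            d.name_standard == name_standard and (role is None or d.role == role)
            for d in self.drugs
        )

    def ps_drugs(self) -> frozenset[str]:
        """Standardized names of the primary-suspect drugs on this report."""
        return frozenset(d.name_standard for d in self.drugs if d.role == "PS")


def assign_age_group(age_years: Optional[float]) -> str:
    """Age band used throughout the demographic summaries.

    <18 | 18-65 (upper-exclusive) | >=65 | unknown.
    """
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-65"
    return ">=65"


@dataclass
class QualityLog:
    """Counts of rows/values set aside during ingestion, never silently dropped."""

    malformed_lines: int = 0
    implausible_ages: int = 0
    partial_dates: int = 0
    eventless_reports: int = 0
    negative_onset: int = 0

    def merge(self, other: "QualityLog") -> "QualityLog":
        return QualityLog(
            **{
                f.name: getattr(self, f.name) + getattr(other, f.name)
                for f in dataclasses.fields(self)
            }
        )

    def to_csv(self) -> str:
        fields = dataclasses.fields(self)
        head = ",".join(f.name for f in fields)
        vals = ",".join(str(getattr(self, f.name)) for f in fields)
        return f"{head}\n{vals}\n"
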