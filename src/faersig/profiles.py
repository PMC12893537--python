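"""Stratified, exclusion, comparator, demographic and time-to-onset analyses.

These reproduce the descriptive and sensitivity layers of a
disproportionality study: demographic n(%) summaries, age/sex strata
each scored against its own stratum background, concomitant
anticoagulant/antiplatelet profiling per event, the
concomitant-exclusion re-analysis, head-to-head comparator runs, and
time-to-onset binning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, build_tables
from .ingest import deduplicate, select_primary_suspect
from .records import (
    AGE_GROUPS,
    OUTCOMES,
    REPORTER_TYPES,
    ROUTES,
    SEX_LEVELS,
    QualityLog,
    ReportRecord,
)
from .stats import MgpsHyperParams, Thresholds, score_tables
from .vocab import ANTITHROMBOTIC_CLASSES, DrugDictionary, VocabularyMap

TTO_BINS = (
    ("0-30", 0, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-120", 91, 120),
    ("121-150", 121, 150),
    ("151-180", 151, 180),
    ("181-360", 181, 360),
    (">360", 361, None),
)


@dataclass(frozen=True)
class StratumSpec:
    """A partition of the report set: by age group or by sex."""

    dimension: str  # "age_group" | "sex"

    def __post_init__(self) -> None:
        if self.dimension not in ("age_group", "sex"):
            raise ValueError("dimension must be 'age_group' or 'sex'")

    @property
    def levels(self) -> tuple[str, ...]:
        return AGE_GROUPS if self.dimension == "age_group" else SEX_LEVELS


def stratify(
    reports: Sequence[ReportRecord], spec: StratumSpec
) -> dict[str, list[ReportRecord]]:
    """Partition reports by the stratum dimension (unknown is a level).

    Each stratum is self-contained: downstream contingency tables compare
    the target drug against the stratum's own other-drug background.
    """
    out: dict[str, list[ReportRecord]] = {level: [] for level in spec.levels}
    for rec in reports:
        out[getattr(rec, spec.dimension)].append(rec)
    return out


# ---------------------------------------------------------------------------
# Concomitant medication profile and exclusion analysis
# ---------------------------------------------------------------------------


def _concomitant_classes(
    rec: ReportRecord, target_drug: str, dictionary: DrugDictionary
) -> set[str]:
    """Antithrombotic classes of the report's non-target drugs (any role)."""
    classes = set()
    for entry in rec.drugs:
        if entry.name_standard == target_drug:
            continue
        cls = dictionary.class_of.get(entry.name_standard, "none")
        if cls in ANTITHROMBOTIC_CLASSES:
            classes.add(cls)
    return classes


CLASS_LABELS = {
    "heparin_lmwh": "Heparin/LMWH",
    "warfarin": "Warfarin",
    "doac": "DOACs",
    "other_anticoagulant": "Other anticoagulants",
    "antiplatelet": "Antiplatelets",
}
NONE_LABEL = "No concomitant anticoagulant/antiplatelet"


def concomitant_profile(
    reports: Sequence[ReportRecord],
    target_drug: str,
    pts: Sequence[str],
    dictionary: DrugDictionary,
) -> pd.DataFrame:
    """Counts/percentages of concomitant antithrombotic classes per event.

    Among target-PS reports mentioning each PT: how many carry at least
    one concomitant drug of each class (rows are not mutually exclusive),
    plus the exclusive none-of-the-classes row. Percentages are per-PT,
    rounded to one decimal.
    """
    target_reports = select_primary_suspect(reports, target_drug)
    rows = []
    for pt in pts:
        with_pt = [r for r in target_reports if pt in r.events]
        n_pt = len(with_pt)
        class_sets = [_concomitant_classes(r, target_drug, dictionary) for r in with_pt]
        for cls in ANTITHROMBOTIC_CLASSES:
            count = sum(1 for s in class_sets if cls in s)
            rows.append(
                {
                    "event": pt,
                    "n_event": n_pt,
                    "medication": CLASS_LABELS[cls],
                    "count": count,
                    "percent": round(100.0 * count / n_pt, 1) if n_pt else 0.0,
                }
            )
        none_count = sum(1 for s in class_sets if not s)
        rows.append(
            {
                "event": pt,
                "n_event": n_pt,
                "medication": NONE_LABEL,
                "count": none_count,
                "percent": round(100.0 * none_count / n_pt, 1) if n_pt else 0.0,
            }
        )
    return pd.DataFrame(rows)


def exclusion_analysis(
    reports: Sequence[ReportRecord],
    target_drug: str,
    dictionary: DrugDictionary,
    vocab: VocabularyMap,
    hyper: MgpsHyperParams,
    level: str = "PT",
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Signal table after dropping every report (target and background)
    that carries any concomitant anticoagulant or antiplatelet drug."""
    kept = [r for r in reports if not _concomitant_classes(r, target_drug, dictionary)]
    if not kept:
        warnings.warn("exclusion analysis removed every report", stacklevel=2)
        return score_tables([], hyper, thresholds)
    tables = build_tables(kept, target_drug, vocab, level=level)
    return score_tables(tables, hyper, thresholds)


def comparator_analysis(
    reports: Sequence[ReportRecord],
    drug_list: Sequence[str],
    vocab: VocabularyMap,
    hyper: MgpsHyperParams,
    pts: Optional[Sequence[str]] = None,
    level: str = "PT",
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """The full PS-filter -> contingency -> scoring chain per comparator.

    Long-format result keyed by (drug, event); identical thresholds for
    every drug. Restricting `pts` keeps only those events.
    """
    blocks = []
    for drug in drug_list:
        tables = build_tables(reports, drug, vocab, level=level)
        if pts is not None:
            keep = set(pts)
            tables = [t for t in tables if t.event_label in keep]
        scored = score_tables(tables, hyper, thresholds)
        scored.insert(0, "drug", drug)
        if len(scored):
            blocks.append(scored)
    if not blocks:
        return pd.DataFrame()
    return pd.concat(blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# Time to onset
# ---------------------------------------------------------------------------


@dataclass
class OnsetSummary:
    """Per-report time to onset (days), binned counts and quartiles."""

    tto_days: list[Optional[int]]
    bin_counts: dict[str, int]
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    n_valid: int
    n_total: int
    quality: QualityLog = field(default_factory=QualityLog)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin": label, "count": self.bin_counts[label],
             "percent": round(100.0 * self.bin_counts[label] / self.n_total, 2) if self.n_total else 0.0}
            for label in list(self.bin_counts)
        ]
        return pd.DataFrame(rows)


def tto_bin(days: Optional[int]) -> str:
    if days is None:
        return "unknown"
    for label, lo, hi in TTO_BINS:
        if days >= lo and (hi is None or days <= hi):
            return label
    return "unknown"  # unreachable for non-negative days


def onset_analysis(reports: Sequence[ReportRecord]) -> OnsetSummary:
    """Time to onset = event onset - therapy start of the first PS drug.

    Same-day onset counts as 0 days. Partial dates are treated as
    missing; negative intervals are excluded and counted in the quality
    log. Bins are inclusive of both printed endpoints.
    """
    qlog = QualityLog()
    tto: list[Optional[int]] = []
    for rec in reports:
        start, onset = rec.therapy_start, rec.event_onset
        if start is None or onset is None or not start.full or not onset.full:
            tto.append(None)
            continue
        days = (onset.date - start.date).days
        if days < 0:
            qlog.negative_onset += 1
            tto.append(None)
            continue
        tto.append(days)
    valid = [t for t in tto if t is not None]
    counts = {label: 0 for label, _, _ in TTO_BINS}
    counts["unknown"] = 0
    for t in tto:
        counts[tto_bin(t)] += 1
    if valid:
        q1, med, q3 = np.percentile(valid, [25, 50, 75])
    else:
        q1 = med = q3 = None
    return OnsetSummary(
        tto_days=tto,
        bin_counts=counts,
        median=None if med is None else float(med),
        q1=None if q1 is None else float(q1),
        q3=None if q3 is None else float(q3),
        n_valid=len(valid),
        n_total=len(tto),
        quality=qlog,
    )


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------


def _level_counts(values: Iterable[str], levels: Sequence[str]) -> list[tuple[str, int]]:
    counts = {lvl: 0 for lvl in levels}
    extra: dict[str, int] = {}
    for v in values:
        if v in counts:
            counts[v] += 1
        else:
            extra[v] = extra.get(v, 0) + 1
    out = list(counts.items())
    out.extend(sorted(extra.items(), key=lambda kv: -kv[1]))
    return out


def demographics(reports: Sequence[ReportRecord]) -> pd.DataFrame:
    """Report-characteristics summary: n(%) per level.

    Sex, age group, reporter type, country, route and onset bins use the
    report count as denominator; outcome percentages use the total number
    of outcome mentions (a report can carry several outcomes). Age and
    time to onset are summarized as median (Q1, Q3).
    """
    n = len(reports)
    rows: list[dict] = []

    def add_block(variable: str, pairs: list[tuple[str, int]], denom: int) -> None:
        for level, count in pairs:
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "count": count,
                    "percent": round(100.0 * count / denom, 2) if denom else 0.0,
                }
            )

    add_block("sex", _level_counts((r.sex for r in reports), SEX_LEVELS), n)

    ages = [r.age_years for r in reports if r.age_years is not None]
    if ages:
        q1, med, q3 = np.percentile(ages, [25, 50, 75])
        rows.append(
            {"variable": "age_years", "level": f"median ({q1:.2f}, {q3:.2f})",
             "count": len(ages), "percent": float(med)}
        )
    add_block("age_group", _level_counts((r.age_group for r in reports), AGE_GROUPS), n)
    add_block(
        "reporter_type",
        _level_counts((r.reporter_type for r in reports), REPORTER_TYPES),
        n,
    )
    country_counts = pd.Series([r.country for r in reports]).value_counts()
    add_block("country", list(country_counts.items()), n)
    add_block("route", _level_counts((r.route for r in reports), ROUTES), n)

    mentions = [oc for r in reports for oc in r.outcomes]
    add_block("outcomes", _level_counts(mentions, OUTCOMES), len(mentions))

    onset = onset_analysis(reports)
    if onset.median is not None:
        rows.append(
            {"variable": "tto_days", "level": f"median ({onset.q1:.2f}, {onset.q3:.2f})",
             "count": onset.n_valid, "percent": onset.median}
        )
    for label, count in onset.bin_counts.items():
        rows.append(
            {"variable": "tto_bin", "level": label, "count": count,
             "percent": round(100.0 * count / n, 2) if n else 0.0}
        )
    return pd.DataFrame(rows)


def stratified_signal_tables(
    reports: Sequence[ReportRecord],
    target_drug: str,
    spec: StratumSpec,
    vocab: VocabularyMap,
    hyper: MgpsHyperParams,
    level: str = "PT",
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Signal tables per stratum, each against its own background."""
    blocks = []
    for stratum, subset in stratify(reports, spec).items():
        if not subset:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables = build_tables(subset, target_drug, vocab, level=level)
        scored = score_tables(tables, hyper, thresholds)
        scored.insert(0, "stratum", stratum)
        blocks.append(scored)
    if not blocks:
        return pd.DataFrame()
    return pd.concat(blocks, ignore_index=True)
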