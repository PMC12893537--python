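"""2x2 drug-event contingency tables from a deduplicated report set.

Counting unit is the unique (report, event-label) pair: a report
contributes at most once to any PT, and at most once per SOC after
rollup. For a target drug (defined by primary-suspect role) and an event
label::

        a = target-drug pairs with the event
    a + b = all pairs contributed by target-drug reports
    a + c = all pairs with the event
        N = all pairs in the dataset

The background is every other drug's pairs in the same dataset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import ReportRecord
from .vocab import VocabularyMap


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    level: str  # "PT" | "SOC"
    event_label: str
    drug_label: str

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the expected count under independence."""
        n = self.n_total
        if n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / n


def report_labels(report: ReportRecord, vocab: VocabularyMap, level: str) -> frozenset[str]:
    """The distinct event labels a report contributes at the given level."""
    if level == "PT":
        return report.events
    if level == "SOC":
        return frozenset(vocab.soc_of(pt) for pt in report.events)
    raise ValueError(f"unknown level {level!r}")


def _pair_frame(
    reports: Sequence[ReportRecord], target_drug: str, vocab: VocabularyMap, level: str
) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(reports):
        is_target = rec.has_drug(target_drug, role="PS")
        for label in report_labels(rec, vocab, level):
            rows.append((i, label, is_target))
    return pd.DataFrame(rows, columns=["report", "label", "target"])


def build_tables(
    reports: Sequence[ReportRecord],
    target_drug: str,
    vocab: VocabularyMap,
    level: str = "PT",
) -> list[ContingencyTable]:
    """One table per event label with a >= 1, sorted by descending a.

    Emits a warning and an empty list when the target drug never appears
    as primary suspect.
    """
    pairs = _pair_frame(reports, target_drug, vocab, level)
    if pairs.empty:
        return []
    n_all = len(pairs)
    target_pairs = pairs[pairs["target"]]
    if target_pairs.empty:
        warnings.warn(
            f"target drug {target_drug!r} absent (as primary suspect) from dataset",
            stacklevel=2,
        )
        return []
    a_plus_b = len(target_pairs)
    a_by_label = target_pairs.groupby("label").size()
    event_margin = pairs.groupby("label").size()
    tables = []
    for label, a in a_by_label.items():
        a = int(a)
        c = int(event_margin[label]) - a
        b = a_plus_b - a
        d = n_all - a - b - c
        tables.append(
            ContingencyTable(a, b, c, d, level=level, event_label=str(label), drug_label=target_drug)
        )
    tables.sort(key=lambda t: (-t.a, t.event_label))
    return tables


def soc_rollup(
    reports: Sequence[ReportRecord], target_drug: str, vocab: VocabularyMap
) -> list[ContingencyTable]:
    """SOC-level tables: each report counts at most once per SOC; PTs
    without a mapping accumulate under the 'unmapped' SOC."""
    return build_tables(reports, target_drug, vocab, level="SOC")


def all_pair_tables(
    reports: Sequence[ReportRecord], vocab: VocabularyMap, level: str = "PT"
) -> pd.DataFrame:
    """(a, E) cells for every (PS drug, event label) pair with a >= 1.

    This is the cell set the gamma-Poisson shrinker is fitted on: each
    drug in turn plays the target role against the rest of the dataset.
    Columns: drug, label, a, b, c, d, E.
    """
    rows = []
    for i, rec in enumerate(reports):
        labels = report_labels(rec, vocab, level)
        for drug in rec.ps_drugs():
            for label in labels:
                rows.append((i, drug, label))
    pairs = pd.DataFrame(rows, columns=["report", "drug", "label"])
    if pairs.empty:
        return pd.DataFrame(columns=["drug", "label", "a", "b", "c", "d", "E"])
    # a report with several PS drugs contributes one pair per (drug, label)
    n_all = len(pairs.drop_duplicates(["report", "label"]))
    event_margin = pairs.drop_duplicates(["report", "label"]).groupby("label").size()
    drug_margin = pairs.groupby("drug").size()
    cells = pairs.groupby(["drug", "label"]).size().rename("a").reset_index()
    cells["b"] = cells["drug"].map(drug_margin) - cells["a"]
    cells["c"] = cells["label"].map(event_margin) - cells["a"]
    cells["d"] = n_all - cells["a"] - cells["b"] - cells["c"]
    cells["E"] = (cells["a"] + cells["b"]) * (cells["a"] + cells["c"]) / n_all
    return cells


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """CSV-ready view: event_label, level, a, b, c, d."""
    return pd.DataFrame(
        [
            {
                "event_label": t.event_label,
                "level": t.level,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
            }
            for t in tables
        ]
    )
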