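"""Shared fixtures: hand-built report sets and small synthetic quarters."""
from __future__ import annotations

import datetime

import pytest

from faersig.records import DrugEntry, ParsedDate, ReportRecord
from faersig.synthetic import default_config, generate
from faersig.vocab import load_default_drug_dictionary, load_toy_vocabulary


def make_report(
    pid: str,
    case: str | None = None,
    drugs: list[tuple[str, str]] = (("fondaparinux", "PS"),),
    events: set[str] = frozenset({"haematoma"}),
    date: str = "20200101",
    **kwargs,
) -> ReportRecord:
    """Compact constructor for hand-built fixtures."""
    d = datetime.date(int(date[:4]), int(date[4:6]), int(date[6:8]))
    return ReportRecord(
        primary_id=pid,
        case_id=case or pid,
        report_date=ParsedDate(d, "day"),
        drugs=[DrugEntry(n, n, role) for n, role in drugs],
        events=frozenset(events),
        **kwargs,
    )


@pytest.fixture(scope="session")
def toy_vocab():
    return load_toy_vocabulary()


@pytest.fixture(scope="session")
def drug_dict():
    return load_default_drug_dictionary()


@pytest.fixture
def five_reports():
    """Two drugs, two PTs: the minimal worked contingency example."""
    return [
        make_report("1", drugs=[("x", "PS")], events={"p"}),
        make_report("2", drugs=[("x", "PS")], events={"q"}),
        make_report("3", drugs=[("y", "PS")], events={"p"}),
        make_report("4", drugs=[("y", "PS")], events={"q"}),
        make_report("5", drugs=[("y", "PS")], events={"p"}),
    ]


@pytest.fixture(scope="session")
def small_synthetic():
    """A 2,000-report synthetic set (deduplicated versions included)."""
    cfg = default_config(n_reports=2000, seed=5)
    return cfg, generate(cfg)
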