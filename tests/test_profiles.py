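"""Strata, concomitant profiling, exclusion/comparator runs, TTO, demographics."""
from __future__ import annotations

import datetime

import pytest

from faersig.contingency import build_tables
from faersig.ingest import deduplicate
from faersig.profiles import (
    NONE_LABEL,
    OnsetSummary,
    StratumSpec,
    comparator_analysis,
    concomitant_profile,
    demographics,
    exclusion_analysis,
    onset_analysis,
    stratify,
    tto_bin,
)
from faersig.records import ParsedDate
from faersig.stats import CANONICAL_HYPERPARAMS, score_tables
from faersig.synthetic import SignalSpec, default_config, generate

from conftest import make_report


def dated(pid, start, onset, **kw):
    rec = make_report(pid, **kw)
    rec.therapy_start = None if start is None else ParsedDate(start, "day")
    rec.event_onset = None if onset is None else ParsedDate(onset, "day")
    return rec


class TestStratify:
    def test_age_boundaries(self):
        ages = {"1": 10.0, "2": 30.0, "3": 70.0, "4": None, "5": 65.0}
        recs = []
        for pid, age in ages.items():
            r = make_report(pid)
            r.age_years = age
            from faersig.records import assign_age_group

            r.age_group = assign_age_group(age)
            recs.append(r)
        strata = stratify(recs, StratumSpec("age_group"))
        assert [r.primary_id for r in strata["<18"]] == ["1"]
        assert [r.primary_id for r in strata["18-65"]] == ["2"]
        assert [r.primary_id for r in strata[">=65"]] == ["3", "5"]  # 65 is >=65
        assert [r.primary_id for r in strata["unknown"]] == ["4"]

    def test_partition_is_exhaustive(self, small_synthetic):
        _, records = small_synthetic
        reports = deduplicate(records)
        strata = stratify(reports, StratumSpec("sex"))
        assert sum(len(v) for v in strata.values()) == len(reports)


class TestConcomitantProfile:
    def test_simple_percentage(self, drug_dict):
        recs = [
            make_report("1", drugs=[("fondaparinux", "PS"), ("heparin", "C")],
                        events={"haematoma"}),
            make_report("2", events={"haematoma"}),
            make_report("3", events={"haematoma"}),
            make_report("4", events={"haematoma"}),
        ]
        prof = concomitant_profile(recs, "fondaparinux", ["haematoma"], drug_dict)
        hep = prof[prof["medication"] == "Heparin/LMWH"].iloc[0]
        assert hep["count"] == 1 and hep["percent"] == 25.0

    def test_hit_like_fraction(self, drug_dict):
        """30 of 115 event reports with concomitant heparin -> 26.1%."""
        recs = []
        for i in range(115):
            drugs = [("fondaparinux", "PS")]
            if i < 30:
                drugs.append(("heparin", "C"))
            recs.append(
                make_report(str(i), drugs=drugs, events={"heparin-induced thrombocytopenia"})
            )
        prof = concomitant_profile(
            recs, "fondaparinux", ["heparin-induced thrombocytopenia"], drug_dict
        )
        hep = prof[prof["medication"] == "Heparin/LMWH"].iloc[0]
        assert hep["count"] == 30 and hep["percent"] == 26.1

    def test_multi_class_counting_and_exclusive_none_row(self, drug_dict):
        recs = [
            make_report("1", drugs=[("fondaparinux", "PS"), ("warfarin", "C"), ("aspirin", "C")],
                        events={"haemorrhage"}),
            make_report("2", events={"haemorrhage"}),
        ]
        prof = concomitant_profile(recs, "fondaparinux", ["haemorrhage"], drug_dict)
        by_med = prof.set_index("medication")
        assert by_med.loc["Warfarin", "count"] == 1
        assert by_med.loc["Antiplatelets", "count"] == 1
        assert by_med.loc[NONE_LABEL, "count"] == 1  # report 1 excluded from none

    def test_absent_pt_gives_zero_row(self, drug_dict):
        prof = concomitant_profile(
            [make_report("1")], "fondaparinux", ["melaena"], drug_dict
        )
        assert (prof["count"] == 0).all()


class TestExclusion:
    def test_no_flagged_drugs_identical_to_main(self, toy_vocab, drug_dict):
        recs = [
            make_report("1", events={"haematoma"}),
            make_report("2", drugs=[("metformin", "PS")], events={"nausea"}),
            make_report("3", drugs=[("metformin", "PS")], events={"haematoma"}),
        ]
        main = score_tables(
            build_tables(recs, "fondaparinux", toy_vocab), CANONICAL_HYPERPARAMS
        )
        excl = exclusion_analysis(
            recs, "fondaparinux", drug_dict, toy_vocab, CANONICAL_HYPERPARAMS
        )
        assert excl.equals(main)

    def test_flagged_reports_removed_everywhere(self, toy_vocab, drug_dict):
        recs = [
            make_report("1", events={"haematoma"}),
            make_report("2", drugs=[("fondaparinux", "PS"), ("warfarin", "C")],
                        events={"haematoma"}),
            make_report("3", drugs=[("metformin", "PS"), ("aspirin", "C")],
                        events={"nausea"}),
            make_report("4", drugs=[("metformin", "PS")], events={"haematoma"}),
            make_report("5", drugs=[("metformin", "PS")], events={"nausea"}),
            make_report("6", drugs=[("omeprazole", "PS")], events={"haematoma"}),
            make_report("7", drugs=[("omeprazole", "PS")], events={"rash"}),
            make_report("8", events={"rash"}),
        ]
        excl = exclusion_analysis(
            recs, "fondaparinux", drug_dict, toy_vocab, CANONICAL_HYPERPARAMS
        )
        # brute-force recount on the 6 unflagged reports (2 and 3 removed)
        kept = [r for r in recs if r.primary_id not in {"2", "3"}]
        expected = score_tables(
            build_tables(kept, "fondaparinux", toy_vocab), CANONICAL_HYPERPARAMS
        )
        assert excl.equals(expected)

    def test_order_invariance(self, toy_vocab, drug_dict, small_synthetic):
        _, records = small_synthetic
        reports = deduplicate(records)[:500]
        cfg_vocab = toy_vocab
        fwd = exclusion_analysis(
            reports, "fondaparinux", drug_dict, cfg_vocab, CANONICAL_HYPERPARAMS
        )
        rev = exclusion_analysis(
            list(reversed(reports)), "fondaparinux", drug_dict, cfg_vocab,
            CANONICAL_HYPERPARAMS,
        )
        assert fwd.equals(rev)


class TestComparator:
    def test_self_comparison_reproduces_main(self, small_synthetic):
        cfg, records = small_synthetic
        reports = deduplicate(records)
        vocab = cfg.vocabulary()
        comp = comparator_analysis(
            reports, ["fondaparinux"], vocab, CANONICAL_HYPERPARAMS
        )
        main = score_tables(
            build_tables(reports, "fondaparinux", vocab), CANONICAL_HYPERPARAMS
        )
        assert comp.drop(columns="drug").equals(main)

    def test_injected_signal_fires_for_one_drug_only(self):
        cfg = default_config(
            n_reports=12_000,
            signals=[SignalSpec("fondaparinux", "pt 150", 25.0)],
            seed=21,
        )
        reports = deduplicate(generate(cfg))
        vocab = cfg.vocabulary()
        comp = comparator_analysis(
            reports, ["fondaparinux", "warfarin"], vocab, CANONICAL_HYPERPARAMS,
            pts=["pt 150"],
        )
        flags = comp.set_index("drug")["flag_combined"]
        assert bool(flags.get("fondaparinux", False))
        assert not bool(flags.get("warfarin", False))


class TestOnset:
    def test_day_arithmetic_and_bins(self):
        recs = [
            dated("1", datetime.date(2020, 1, 1), datetime.date(2020, 1, 6)),
        ]
        s = onset_analysis(recs)
        assert s.tto_days == [5]
        assert s.bin_counts["0-30"] == 1

    def test_negative_interval_excluded_and_logged(self):
        recs = [dated("1", datetime.date(2020, 2, 1), datetime.date(2020, 1, 1))]
        s = onset_analysis(recs)
        assert s.tto_days == [None]
        assert s.quality.negative_onset == 1

    @pytest.mark.parametrize(
        "days,bin_label",
        [(0, "0-30"), (30, "0-30"), (31, "31-60"), (180, "151-180"),
         (181, "181-360"), (360, "181-360"), (361, ">360")],
    )
    def test_bin_edges_inclusive(self, days, bin_label):
        assert tto_bin(days) == bin_label

    def test_bins_partition_reports(self, small_synthetic):
        _, records = small_synthetic
        reports = deduplicate(records)
        s = onset_analysis(reports)
        assert sum(s.bin_counts.values()) == len(reports)
        assert isinstance(s, OnsetSummary)

    def test_partial_dates_are_missing_for_tto(self):
        rec = dated("1", None, None)
        rec.therapy_start = ParsedDate(datetime.date(2020, 3, 1), "month")
        rec.event_onset = ParsedDate(datetime.date(2020, 3, 15), "day")
        assert onset_analysis([rec]).tto_days == [None]


class TestDemographics:
    def test_all_unknown_sex(self):
        recs = [make_report(str(i)) for i in range(4)]
        df = demographics(recs)
        sex = df[(df["variable"] == "sex") & (df["level"] == "unknown")].iloc[0]
        assert sex["count"] == 4 and sex["percent"] == 100.0

    def test_outcome_denominator_is_mention_total(self):
        recs = [
            make_report("1", outcomes=frozenset({"death", "hospitalization"})),
            make_report("2", outcomes=frozenset({"hospitalization"})),
            make_report("3"),
        ]
        df = demographics(recs)
        out = df[df["variable"] == "outcomes"].set_index("level")
        # 3 mentions total: hospitalization 2/3, death 1/3
        assert out.loc["hospitalization", "percent"] == pytest.approx(66.67, abs=0.01)
        assert out.loc["death", "percent"] == pytest.approx(33.33, abs=0.01)

    def test_exclusive_blocks_sum_to_100(self, small_synthetic):
        _, records = small_synthetic
        reports = deduplicate(records)
        df = demographics(reports)
        for var in ("sex", "age_group", "route", "outcomes"):
            total = df[df["variable"] == var]["percent"].sum()
            assert total == pytest.approx(100.0, abs=0.1)
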