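"""Synthetic FAERS-style report generator with known ground truth.

Emulates the structure of spontaneous-report data: multi-drug
multi-event reports with role codes, duplicate case versions,
demographic fields with configurable missingness, therapy/event dates,
and designated drug-event pairs whose reporting rate is elevated by a
multiplicative factor rho on the PT selection weights of the
primary-suspect drug. The induced contingency cells are available in
closed form through :func:`expected_tables`, so estimator bias and
type-I/power behaviour can be checked against an analytic oracle.

Mechanics per report: the first drug drawn is the primary suspect (the
rest are concomitants); the event count k is zero-truncated Poisson; k
PT draws are made i.i.d. from the (re-weighted, renormalized) PT
probabilities and collapse to the distinct set. With probability
`duplicate_rate` an earlier-dated version of the case is also emitted,
differing only in primary_id and report date.
"""
from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .records import DrugEntry, ParsedDate, ReportRecord, assign_age_group
from .vocab import VocabularyMap

EPOCH = datetime.date(2015, 1, 1)  # therapy-start window origin
START_WINDOW_DAYS = 1826  # 2015-01-01 .. 2019-12-31


@dataclass(frozen=True)
class SignalSpec:
    """Reporting-rate multiplier rho for one (PS drug, PT) pair; rho = 1 is null."""

    drug: str
    pt: str
    rho: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ConfigError("signal rho must be positive")


@dataclass
class SyntheticConfig:
    """Full generative specification for one synthetic report set.

    Defaults (see :func:`default_config`) mirror the marginal structure
    of a fondaparinux-like FAERS extract: report-level demographic
    proportions, about three events per report, a subcutaneous-dominant
    route mix, exponential time-to-onset with median ~5 days, and a third
    of reports missing onset information.
    """

    n_reports: int
    drug_catalog: list[tuple[str, str, float]]  # (name, class, marginal use prob)
    pt_catalog: list[tuple[str, str, float]]  # (PT, SOC, baseline prob)
    signals: list[SignalSpec] = field(default_factory=list)
    events_per_report: float = 3.0  # zero-truncated Poisson rate
    drugs_per_report: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.30, 3: 0.15, 4: 0.05}
    )
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"female": 0.4872, "male": 0.3497, "unknown": 0.1631}
    )
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: {"<18": 0.0054, "18-65": 0.2726, ">=65": 0.3924, "unknown": 0.3296}
    )
    route_probs: dict[str, float] = field(
        default_factory=lambda: {
            "subcutaneous": 0.7234,
            "other": 0.2349,
            "intravenous": 0.0318,
            "oral": 0.0038,
            "transplacental": 0.0035,
            "intramuscular": 0.0026,
        }
    )
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Consumer": 0.4591,
            "Physician": 0.3315,
            "Pharmacist": 0.0907,
            "Other health-professional": 0.0900,
            "unknown": 0.0273,
            "Lawyer": 0.0007,
            "Registered Nurse": 0.0007,
        }
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {
            "unknown": 0.6621,
            "US": 0.1284,
            "FR": 0.0871,
            "IE": 0.0527,
            "IT": 0.0340,
            "DE": 0.0168,
            "JP": 0.0102,
            "GB": 0.0087,
        }
    )
    outcome_count_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.15, 1: 0.55, 2: 0.30}
    )
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {
            "hospitalization": 0.4184,
            "other_serious": 0.2962,
            "death": 0.1507,
            "life_threatening": 0.0967,
            "disability": 0.0297,
            "required_intervention": 0.0053,
            "congenital_anomaly": 0.0030,
        }
    )
    tto_mean_days: float = 7.2  # exponential mean; median ~5 days
    onset_missing_rate: float = 0.33
    duplicate_rate: float = 0.15
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        if not self.drug_catalog or not self.pt_catalog:
            raise ConfigError("drug and PT catalogs must be non-empty")
        for _, _, p in self.drug_catalog + self.pt_catalog:
            if p < 0:
                raise ConfigError("catalog probabilities must be non-negative")
        drug_names = {d for d, _, _ in self.drug_catalog}
        pt_names = {p for p, _, _ in self.pt_catalog}
        for sig in self.signals:
            if sig.drug not in drug_names:
                raise ConfigError(f"signal drug {sig.drug!r} not in drug catalog")
            if sig.pt not in pt_names:
                raise ConfigError(f"signal PT {sig.pt!r} not in PT catalog")
        for probs in (
            self.sex_probs, self.age_group_probs, self.route_probs,
            self.reporter_probs, self.country_probs, self.outcome_probs,
        ):
            if any(v < 0 or v > 1 for v in probs.values()):
                raise ConfigError("level probabilities must lie in [0, 1]")
        if self.events_per_report <= 0 or self.tto_mean_days <= 0:
            raise ConfigError("rates must be positive")
        if not (0 <= self.duplicate_rate < 1) or not (0 <= self.onset_missing_rate <= 1):
            raise ConfigError("rates must be valid probabilities")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signals"] = [dataclasses.asdict(s) for s in self.signals]
        d["drug_catalog"] = [list(t) for t in self.drug_catalog]
        d["pt_catalog"] = [list(t) for t in self.pt_catalog]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["signals"] = [SignalSpec(**s) for s in d.get("signals", [])]
        d["drug_catalog"] = [tuple(t) for t in d["drug_catalog"]]
        d["pt_catalog"] = [tuple(t) for t in d["pt_catalog"]]
        for key in ("drugs_per_report", "outcome_count_probs"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- derived views ------------------------------------------------------

    def vocabulary(self) -> VocabularyMap:
        """PT -> SOC map induced by the catalog."""
        pt_to_soc = {pt: soc for pt, soc, _ in self.pt_catalog}
        order: list[str] = []
        for _, soc, _ in self.pt_catalog:
            if soc not in order:
                order.append(soc)
        return VocabularyMap(pt_to_soc=pt_to_soc, soc_list=order)

    def drug_marginals(self) -> np.ndarray:
        p = np.array([q for _, _, q in self.drug_catalog], dtype=float)
        return p / p.sum()

    def pt_weights(self, ps_drug: Optional[str] = None) -> np.ndarray:
        """Normalized PT selection weights given the PS drug (rho applied)."""
        w = np.array([q for _, _, q in self.pt_catalog], dtype=float)
        if ps_drug is not None:
            idx = {pt: i for i, (pt, _, _) in enumerate(self.pt_catalog)}
            for sig in self.signals:
                if sig.drug == ps_drug:
                    w[idx[sig.pt]] *= sig.rho
        return w / w.sum()


def default_config(
    n_reports: int = 50_000,
    signals: Sequence[SignalSpec] = (),
    seed: int = 0,
    n_pts: int = 240,
) -> SyntheticConfig:
    """Study-scale default: ~25 drugs, >= 200 PTs over 25 SOCs, Zipf-like
    marginals, demographic mix per the defaults above."""
    from .vocab import load_default_drug_dictionary, load_toy_vocabulary

    vocab = load_toy_vocabulary()
    toy_pts = sorted(vocab.pt_to_soc)
    socs = vocab.soc_list
    pt_catalog: list[tuple[str, str, float]] = []
    for i, pt in enumerate(toy_pts):
        pt_catalog.append((pt, vocab.pt_to_soc[pt], 1.0 / (i + 5)))
    i = len(pt_catalog)
    while len(pt_catalog) < n_pts:
        pt_catalog.append((f"pt {i:03d}", socs[i % len(socs)], 1.0 / (i + 5)))
        i += 1
    ddict = load_default_drug_dictionary()
    drugs = sorted(ddict.class_of)
    drug_catalog = [
        (name, ddict.class_of[name], 1.0 / (j + 3)) for j, name in enumerate(drugs)
    ]
    cfg = SyntheticConfig(
        n_reports=n_reports,
        drug_catalog=drug_catalog,
        pt_catalog=pt_catalog,
        signals=list(signals),
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _rng(seed: int) -> np.random.Generator:
    # counter-based generator: draw order is the only coupling between draws
    return np.random.Generator(np.random.Philox(seed))


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (rejection of zeros)."""
    k = rng.poisson(lam, size)
    while True:
        zero = k == 0
        if not zero.any():
            return k
        k[zero] = rng.poisson(lam, int(zero.sum()))


def _choice_dict(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.array(keys, dtype=object)[idx]


def generate(config: SyntheticConfig, seed: Optional[int] = None) -> list[ReportRecord]:
    """Generate the full report set, duplicate case versions included.

    Fully reproducible from (config, seed); `seed` overrides config.seed.
    Deduplicating the output recovers exactly `n_reports` records.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_reports
    drug_names = [d for d, _, _ in config.drug_catalog]
    pt_names = np.array([p for p, _, _ in config.pt_catalog], dtype=object)
    marg = config.drug_marginals()

    ps_idx = rng.choice(len(drug_names), size=n, p=marg)
    k_events = _zt_poisson(rng, config.events_per_report, n)

    # PT draws, grouped by PS drug so signal re-weighting applies per drug
    event_sets: list[set] = [set() for _ in range(n)]
    signal_drugs = {s.drug for s in config.signals}
    for g, name in enumerate(drug_names):
        mask = ps_idx == g
        if not mask.any():
            continue
        w = config.pt_weights(name if name in signal_drugs else None)
        ks = k_events[mask]
        draws = rng.choice(len(pt_names), size=int(ks.sum()), p=w)
        offsets = np.concatenate([[0], np.cumsum(ks)])
        for j, ridx in enumerate(np.flatnonzero(mask)):
            event_sets[ridx] = set(pt_names[draws[offsets[j]:offsets[j + 1]]])

    # concomitant drugs
    n_drugs_per = _choice_dict(rng, {k: v for k, v in config.drugs_per_report.items()}, n)
    extras_count = np.maximum(np.asarray(n_drugs_per, dtype=int) - 1, 0)
    extra_draws = rng.choice(len(drug_names), size=int(extras_count.sum()), p=marg)
    offsets = np.concatenate([[0], np.cumsum(extras_count)])

    sex = _choice_dict(rng, config.sex_probs, n)
    age_group = _choice_dict(rng, config.age_group_probs, n)
    age_lo = {"<18": 1.0, "18-65": 18.0, ">=65": 65.0}
    age_hi = {"<18": 17.9, "18-65": 64.9, ">=65": 95.0}
    age_u = rng.uniform(0.0, 1.0, n)
    route = _choice_dict(rng, config.route_probs, n)
    reporter = _choice_dict(rng, config.reporter_probs, n)
    country = _choice_dict(rng, config.country_probs, n)
    n_outc = np.asarray(
        _choice_dict(rng, {k: v for k, v in config.outcome_count_probs.items()}, n),
        dtype=int,
    )
    outc_draws = _choice_dict(rng, config.outcome_probs, int(n_outc.sum()))
    outc_offsets = np.concatenate([[0], np.cumsum(n_outc)])

    start_day = rng.integers(0, START_WINDOW_DAYS, n)
    tto = np.floor(rng.exponential(config.tto_mean_days, n)).astype(int)
    lag = rng.integers(0, 90, n)
    onset_missing = rng.uniform(0.0, 1.0, n) < config.onset_missing_rate
    dup = rng.uniform(0.0, 1.0, n) < config.duplicate_rate
    dup_back = rng.integers(30, 200, n)

    records: list[ReportRecord] = []
    for i in range(n):
        case_id = str(100000 + i)
        ag = age_group[i]
        if ag == "unknown":
            age_years = None
        else:
            age_years = float(age_lo[ag] + age_u[i] * (age_hi[ag] - age_lo[ag]))
        start = EPOCH + datetime.timedelta(days=int(start_day[i]))
        onset = start + datetime.timedelta(days=int(tto[i]))
        fda = onset + datetime.timedelta(days=int(lag[i]))
        drugs = [DrugEntry(drug_names[ps_idx[i]], drug_names[ps_idx[i]], "PS")]
        seen = {ps_idx[i]}
        for g in extra_draws[offsets[i]:offsets[i + 1]]:
            if g not in seen:
                seen.add(g)
                drugs.append(DrugEntry(drug_names[g], drug_names[g], "C"))
        rec = ReportRecord(
            primary_id=case_id + "2",
            case_id=case_id,
            report_date=ParsedDate(fda, "day"),
            sex=str(sex[i]),
            age_years=age_years,
            age_group=assign_age_group(age_years),
            reporter_type=str(reporter[i]),
            country=str(country[i]),
            route=str(route[i]),
            outcomes=frozenset(outc_draws[outc_offsets[i]:outc_offsets[i + 1]]),
            drugs=drugs,
            events=frozenset(event_sets[i]),
            therapy_start=None if onset_missing[i] else ParsedDate(start, "day"),
            event_onset=None if onset_missing[i] else ParsedDate(onset, "day"),
        )
        records.append(rec)
        if dup[i]:
            earlier = dataclasses.replace(
                rec,
                primary_id=case_id + "1",
                report_date=ParsedDate(fda - datetime.timedelta(days=int(dup_back[i])), "day"),
            )
            records.append(earlier)
    return records


def write_ascii(
    config: SyntheticConfig, outdir, seed: Optional[int] = None, quarter: str = "24Q1"
):
    """Generate and write the FAERS ASCII dialect; returns the file paths."""
    from .ingest import records_to_tables, write_tables

    records = generate(config, seed=seed)
    return write_tables(records_to_tables(records), outdir, quarter=quarter)


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------


def _ztp_pgf(lam: float, s: np.ndarray) -> np.ndarray:
    """E[s^k] for zero-truncated Poisson(lam)."""
    return (np.exp(lam * s) - 1.0) / (np.exp(lam) - 1.0)


def expected_tables(config: SyntheticConfig) -> pd.DataFrame:
    """Closed-form expected contingency cells per (drug, PT) pair.

    A report with PS drug D includes PT t with probability
    1 - G(1 - w_t(D)) where G is the zero-truncated Poisson pgf of the
    event count and w_t(D) the renormalized (rho-weighted) selection
    probability. Expected cells follow by linearity over reports.
    Columns: drug, label, a, b, c, d (continuous), plus ror.
    """
    config.validate()
    n = config.n_reports
    drug_names = [d for d, _, _ in config.drug_catalog]
    pt_names = [p for p, _, _ in config.pt_catalog]
    marg = config.drug_marginals()
    lam = config.events_per_report

    incl = np.empty((len(drug_names), len(pt_names)))
    for g, name in enumerate(drug_names):
        w = config.pt_weights(name)
        incl[g] = 1.0 - _ztp_pgf(lam, 1.0 - w)
    pairs_per_report = incl.sum(axis=1)  # mean distinct labels given PS drug
    exp_n = n * float(marg @ pairs_per_report)
    event_margin = n * (marg @ incl)  # expected a+c per PT

    rows = []
    for g, dname in enumerate(drug_names):
        a_row = n * marg[g] * incl[g]
        ab = n * marg[g] * pairs_per_report[g]
        for t, pt in enumerate(pt_names):
            a = a_row[t]
            b = ab - a
            c = event_margin[t] - a
            d = exp_n - a - b - c
            rows.append((dname, pt, a, b, c, d))
    df = pd.DataFrame(rows, columns=["drug", "label", "a", "b", "c", "d"])
    df["ror"] = df["a"] * df["d"] / (df["b"] * df["c"])
    return df


def expected_ror(config: SyntheticConfig, drug: str, pt: str) -> float:
    df = expected_tables(config)
    row = df[(df["drug"] == drug) & (df["label"] == pt)]
    if row.empty:
        raise KeyError(f"({drug!r}, {pt!r}) not in catalogs")
    return float(row["ror"].iloc[0])
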