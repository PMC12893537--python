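# faersig

Disproportionality signal detection for spontaneous adverse-event
report data in the FAERS quarterly ASCII dialect.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect unsolicited reports of suspected adverse drug
reactions. Because there is no denominator of exposed patients, drug
safety signals are screened by *disproportionality*: for a drug–event
pair, the 2×2 table

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| all other drugs| c            | d            |

is built over all reports (here: over unique report × event-label
pairs), and the observed reporting rate is compared with the
independence expectation E = (a+b)(a+c)/N. `faersig` implements the
four standard statistics jointly:

- **ROR** = ad/bc, with Woolf 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`
- **PRR** = [a/(a+b)]/[c/(c+d)], with its CI and the Pearson
  χ² = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]
- **BCPNN information component** IC = log₂((a+½)/(E+½)), with IC025
  the base-2 log of the 2.5 % quantile of a Gamma(a+½, rate E+½)
  posterior
- **MGPS/EBGM**: the empirical-Bayes geometric mean of the
  reporting-rate ratio λ under a two-component gamma mixture prior
  fitted by marginal maximum likelihood across all drug–event cells,
  with EB05 the 5 % posterior quantile

A pair is a *signal* when all four criteria hold — ROR CI lower bound
> 1; PRR ≥ 2 with χ² ≥ 4; IC025 > 0; EB05 > 1 — with at least three
case reports.

Around the statistics sits a complete pipeline: a strict reader/writer
for the dollar-delimited FAERS tables (DEMO/DRUG/REAC/OUTC/THER),
case-version deduplication, primary-suspect selection, a PT→SOC
vocabulary layer (MedDRA is licensed, so a toy vocabulary ships for
testing), demographic and time-to-onset profiling, age/sex-stratified
and concomitant-exclusion re-analyses, comparator runs across
anticoagulant classes, and a synthetic report generator with an
analytic oracle so every stage is testable without any database
download.

## Worked example

Generate a 50,000-report synthetic dataset in which the pair
(fondaparinux, "pt 150") has its reporting rate multiplied by ρ = 10,
then run the full analysis:

```python
import yaml
from faersig.synthetic import default_config, SignalSpec

cfg = default_config(n_reports=50_000,
                     signals=[SignalSpec("fondaparinux", "pt 150", 10.0)],
                     seed=1)
run = {"target_drug": "fondaparinux", "synthetic": cfg.to_dict(),
       "comparators": ["enoxaparin", "heparin", "rivaroxaban"], "seed": 1}
yaml.safe_dump(run, open("demo.yaml", "w"))
```

```sh
faersig analyze --config demo.yaml --out demo_out
faersig report demo_out --top 3
```

prints the per-stage manifest and the detected signals:

```
{
 "contingency_pt": 238,
 "contingency_soc": 25,
 "dedup": 50000,
 "exclusion_signals": 1,
 "ingest": 57563,
 "ps_filter": 1240,
 "signals_pt": 1,
 "signals_soc": 0
}
event_label  n_cases      ror  ror_low  ror_high      prr       chi2       ic    ic025     ebgm     eb05
     pt 150       61 9.203612 6.957569 12.174722 9.070556 358.070468 2.847592 2.462656 1.142301 1.054353
```

Reading this: 57,563 report versions were written (duplicate case
versions included), deduplication recovers exactly the 50,000 cases,
and 1,240 of them carry fondaparinux as primary suspect. Exactly one
PT-level pair passes the joint four-algorithm criterion — the injected
one — with ROR 9.2 (95 % CI 7.0–12.2) covering the analytic induced
odds ratio (≈ 9.8 for this pair; weight renormalization makes it
slightly below ρ). Note the heavy shrinkage of EBGM (1.14): the mixture
prior is fitted to this dataset, whose background is homogeneous by
construction, so the empirical-Bayes route is by far the most
conservative of the four here. The signal also survives the
concomitant-exclusion re-analysis (`exclusion_signals: 1`); no SOC
reaches the joint criterion because the injected PT is diluted within
its organ class.

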