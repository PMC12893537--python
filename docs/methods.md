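# Methods

## Data model and counting conventions

A *report* is one spontaneous safety report: a case identifier, a
version identifier (`primaryid`), demographics, a list of drug mentions
with role codes (PS primary suspect, SS secondary suspect, C
concomitant, I interacting; unrecognized codes collapse to C), a set of
MedDRA preferred terms (PTs), outcome codes, and therapy/event dates.

**Deduplication.** Cases are grouped on the case identifier alone; the
surviving version is the one with the latest report date, ties broken
by the larger `primaryid` (deterministic, and monotone with FAERS id
issuance). Partial dates (YYYYMM or YYYY) are padded with 01 so they
still order versions, but they are flagged and never used for
day-resolution arithmetic.

**Counting unit.** All contingency tables count unique
(report, event-label) pairs: a report contributes at most once to a PT
even if the PT is listed twice, and at most once per SOC after rollup.
This reproduces both report-level SOC counting ("case reports" per
organ class) and event-level margins, and is the dominant convention in
spontaneous-report disproportionality work. The background for a target
drug is everything else in the same deduplicated dataset; "target"
membership requires the primary-suspect role. Tables with a = 0 are not
emitted (the signal criterion requires ≥ 3 cases regardless).

**Vocabulary.** Each PT maps to exactly one SOC (primary-SOC
convention). MedDRA is licensed and is not distributed; the bundled
`toy_meddra.tsv` is a synthetic stand-in covering the 25 standard SOCs
with ~58 PTs. PTs missing from the user vocabulary accumulate under an
explicit `unmapped` SOC rather than failing. Grouping of clinically
overlapping PTs is left to an optional user-supplied two-column file
(`load_pt_groups`); no grouping is hard-coded.

## Disproportionality statistics

For a table (a, b, c, d), N = a+b+c+d, E = (a+b)(a+c)/N:

- ROR = ad/bc; 95 % CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- PRR = [a/(a+b)]/[c/(c+d)];
  CI exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
- Pearson χ² = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]; a Yates-corrected
  variant (|ad−bc| → max(0, |ad−bc|−N/2)) is available but off by
  default — at the case counts where signals are declared the two are
  practically indistinguishable, and the uncorrected statistic pairs
  with the PRR ≥ 2 & χ² ≥ 4 rule as conventionally stated. A degenerate
  margin yields χ² = 0 with a warning.
- Zero cells: the Haldane–Anscombe correction (+0.5 on every cell) is
  applied to ROR and PRR and the result is flagged `corrected`. The
  correction lives in the statistics layer; tables keep raw counts.
- BCPNN: IC = log₂((a+0.5)/(E+0.5)). IC025 is log₂ of the 2.5 %
  quantile of Gamma(shape a+0.5, rate E+0.5) — the two-parameter gamma
  convention, chosen because it reproduces the printed IC/IC025 pairs
  of the modeled study exactly (IC = log₂ EBGM on every SOC row). The
  quantile comes from `scipy.stats.gamma.ppf` (relative accuracy well
  beyond the 1e-10 contract) and is verified in the tests against
  numeric CDF inversion by quadrature.
- MGPS: the reporting-rate ratio λ has a two-component gamma mixture
  prior with parameters (α₁, β₁, α₂, β₂, p). The marginal of a count is
  the corresponding negative-binomial mixture; hyperparameters maximize
  the summed marginal log-likelihood over every (PS-drug, PT) cell of
  the dataset, via L-BFGS-B from the canonical start
  (0.2, 0.1, 2.0, 4.0, 1/3) with box constraints (all ≥ 1e-6, p inside
  (0,1)) and a log-likelihood improvement tolerance of 1e-8.
  Non-convergence returns best-so-far with a flag. The posterior is the
  weighted pair of Gamma(αᵢ+a, βᵢ+E) components;
  EBGM = exp(ΣᵢQᵢ(ψ(αᵢ+a) − ln(βᵢ+E))) and EB05 solves the mixture CDF
  = 0.05 by root bracketing between the component quantiles to absolute
  tolerance 1e-8 — exactness over speed at desk scale; no data
  squashing is implemented because the cell counts here never require
  it.

**Joint criterion.** Signal ⇔ ROR CI low > 1 (strict), PRR ≥ 2 with
χ² ≥ 4 (inclusive), IC025 > 0, EB05 > 1, and n ≥ 3 cases. The four
rules can be toggled individually and combined by conjunction (default)
or disjunction; below the case minimum a pair is never a signal.

## Profiles and sensitivity analyses

- **Demographics**: n(%) per level for sex, age group (<18 / 18–65
  upper-exclusive / ≥65 / unknown), reporter, country, route; age and
  time-to-onset as median (Q1, Q3). Outcome percentages are taken over
  the total of outcome *mentions* (a report may carry several), which
  is the only denominator that reproduces the modeled study's printed
  outcome column; all other blocks use the report count.
- **Time to onset** = event onset − therapy start of the first
  primary-suspect drug entry, in whole days; same-day onset is 0.
  Partial dates are missing; negative intervals are excluded and
  counted in the quality log. Bins 0–30, 31–60, …, 181–360, >360 are
  inclusive of both endpoints; both the valid-only and including-unknown
  totals are reported because spontaneous data leave that denominator
  ambiguous.
- **Strata** (age group or sex) partition the reports, and each stratum
  is scored against its own stratum's background — stand-alone 2×2
  per stratum, so stratum cells add exactly to the pooled table.
- **Concomitant profile**: among target-PS reports mentioning a PT,
  the fraction carrying ≥ 1 non-target drug (any role) in each
  antithrombotic class (heparin/LMWH, warfarin, DOAC, other
  anticoagulant, antiplatelet). Class rows are not mutually exclusive;
  the none-row is exclusive of all of them.
- **Exclusion analysis** drops every report — target and background
  alike — containing any concomitant drug of those classes (other than
  the target itself) and reruns the contingency/scoring chain.
- **Comparator analysis** repeats the entire PS-filter → contingency →
  scoring chain per comparator with identical thresholds, long-format
  keyed by (drug, event).

## Synthetic generator

The generator emulates the structure of FAERS-style data with known
ground truth. Per report: the first drug drawn is the primary suspect
(the rest concomitants); the event count k is zero-truncated Poisson;
k PT draws are made i.i.d. from the PT probabilities — re-weighted
multiplicatively by ρ for designated (PS drug, PT) pairs and
renormalized — and collapse to the distinct set; demographics come from
configurable level probabilities including missing mass; therapy start
is uniform over a five-year window, onset = start + ⌊Exp(mean)⌋ days;
with probability `duplicate_rate` an earlier-dated extra version of the
case is emitted, differing only in `primaryid` and report date. All
draws flow through one counter-based generator (Philox) seeded once, so
output is byte-reproducible from (config, seed).

Default conditions mirror the marginal structure of a
fondaparinux-like FAERS extract: 27 drugs and 240 PTs over 25 SOCs with
Zipf-like marginals; sex 48.7 % female / 35.0 % male / 16.3 % unknown;
age bands 0.5 / 27.3 / 39.2 / 33.0 %; route 72.3 % subcutaneous;
reporter mix led by consumers (45.9 %) and physicians (33.2 %); ~1.15
outcome mentions per report with the hospitalization-led code mix;
about three events per report; exponential time-to-onset with mean 7.2
days (median ≈ 5, matching the modeled study's median with Q1–Q3
1–14); a third of reports missing onset information; 15 % duplicate
case versions.

Because PT draws are i.i.d.-with-replacement before collapsing, the
inclusion probability of PT t for PS drug D is closed-form:
P = 1 − G(1 − w_t(D)), with G the zero-truncated Poisson pgf
G(s) = (e^{λs} − 1)/(e^λ − 1) and w_t(D) the renormalized selection
weight. `expected_tables` turns this into exact expected contingency
cells — the oracle used for estimator-bias and power checks. Two
consequences worth knowing: the induced odds ratio for an injected pair
is slightly below ρ (renormalization spreads the inflation over the
other PTs; for a rare PT the gap is ~2 %, for a high-baseline PT it can
exceed 10 %), so recovery tests compare against the analytic induced
value, and injected-signal studies place ρ on a rare PT where the
induced ratio ≈ ρ.

What the generator does **not** emulate: reporting waves over calendar
time, country-specific reporting behaviour, drug-name misspellings
(standardization is exercised only through dictionary aliases),
correlated event co-occurrence beyond shared SOC membership, and
exposure-driven confounding. Passing the null/power suites therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to the biases of real spontaneous data.

## Numerical and design notes

- The empirical-Bayes prior fitted to the homogeneous synthetic null is
  very tight around λ = 1 (that is the maximum-likelihood answer when
  the background truly is homogeneous), so EBGM/EB05 is the most
  conservative of the four algorithms on synthetic data — an injected
  ρ = 10 pair needs on the order of 50+ cases before EB05 clears 1. On
  real heterogeneous databases the fitted prior is diffuse and EBGM
  tracks PRR at large counts; the large-count limit (EBGM → a/E within
  1 %) is exercised at SOC-scale counts in the tests.
- The two-component mixture is not identifiable when the data are truly
  single-component: the fit may return two near-identical components
  with split weight. Tests assert the substantive collapse (component
  means near truth, likelihood ≥ single-component ML) rather than a
  weight threshold.
- 2×2 reconstruction from printed summaries (`reconstruct_2x2`) solves
  ad/bc = ROR, the PRR identity and the Woolf variance implied by the
  printed CI for (b, c, d) in log space by Newton iteration from a
  starting point derived from the ROR/PRR ratio identity
  ROR/PRR = d(a+b)/(b(c+d)). With 4-significant-digit inputs the
  recomputed χ² is reproducible to ~2 %.
- Problem sizes used by the test suite — 50,000 reports for the
  null/power studies, 10,000 cells for hyperparameter recovery,
  5k/20k/80k replicates for the contraction check — are the package's
  chosen desk-scale study conditions; the full suite runs in well under
  a minute.
- No multiple-testing correction is applied anywhere: disproportionality
  screening conventionally reports all pairs passing the joint
  criterion, and the joint four-algorithm conjunction is itself the
  false-positive control (the measured null rate at study scale is 0 of
  ~6,000 eligible pairs).

## Known limitations

Dictionary-based drug standardization only (exact/alias lookup, no
NLP); single primary SOC per PT (no multi-axiality, LLT/HLT levels or
SMQs); no MedDRA version management; country summarized descriptively;
no plotting layer. Reported associations from any spontaneous-report
analysis are reporting disproportions, not incidence or causal
effects.
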