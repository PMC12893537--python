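"""Disproportionality statistics and joint signal criteria.

Four measures are computed for each 2x2 table (cells a, b, c, d; total N;
E = (a+b)(a+c)/N):

* ROR  = ad/bc with a Woolf 95% CI, exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).
* PRR  = [a/(a+b)] / [c/(c+d)] with CI exp(ln PRR +/- 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))
  and the Pearson chi-square N(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)].
* BCPNN information component IC = log2((a+0.5)/(E+0.5)); its lower 95%
  credibility bound IC025 is the base-2 log of the 2.5% quantile of a
  Gamma(a+0.5, rate E+0.5) posterior.
* MGPS/EBGM: empirical-Bayes geometric mean of the reporting-rate ratio
  under a two-component gamma mixture prior fitted by marginal maximum
  likelihood over all drug-event cells; EB05 is the 5% posterior quantile.

Signal criterion (joint): ROR CI lower bound > 1; PRR >= 2 with
chi-square >= 4; IC025 > 0; EB05 > 1; and at least `min_cases` reports.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .contingency import ContingencyTable

Z95 = 1.96  # normal quantile used by the Woolf-type intervals


@dataclass(frozen=True)
class Estimate:
    value: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied

    def as_tuple(self) -> tuple[float, tuple[float, float]]:
        return self.value, (self.ci_low, self.ci_high)


def _cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0.0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


def ror(table: ContingencyTable) -> Estimate:
    """Reporting odds ratio with Woolf 95% CI.

    Zero cells trigger the Haldane-Anscombe correction (+0.5 to every
    cell); the result is flagged as corrected.
    """
    a, b, c, d, corrected = _cells(table)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), corrected)


def prr(table: ContingencyTable) -> Estimate:
    """Proportional reporting ratio with 95% CI."""
    a, b, c, d, corrected = _cells(table)
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return Estimate(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), corrected)


def pearson_chi2(
    a: float, b: float, c: float, d: float, yates: bool = False
) -> float:
    """Pearson chi-square of a 2x2 table given as raw (possibly non-integer) cells."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0 or n == 0:
        warnings.warn("degenerate 2x2 margin; chi-square defined as 0", stacklevel=2)
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / denom


def chi_square(table: ContingencyTable, yates: bool = False) -> float:
    return pearson_chi2(table.a, table.b, table.c, table.d, yates=yates)


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float]:
    """Information component and its lower 95% credibility bound.

    IC = log2((a+0.5)/(E+0.5)); IC025 = log2 of the 2.5% quantile of
    Gamma(shape a+0.5, rate E+0.5). a = 0 is allowed (shrunk toward null).
    """
    a = float(table.a)
    e = table.expected
    if e <= 0:
        raise ValueError("BCPNN requires E > 0 (both margins positive)")
    return ic_from_counts(a, e)


def ic_from_counts(a: float, e: float) -> tuple[float, float]:
    shape = a + 0.5
    rate = e + 0.5
    ic = math.log2(shape / rate)
    q = sps.gamma.ppf(0.025, shape, scale=1.0 / rate)
    return ic, math.log2(q)


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

#: canonical optimizer start for the mixture prior
MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class MgpsHyperParams:
    """Two-component gamma mixture prior on the reporting-rate ratio.

    Component i is Gamma(shape alpha_i, rate beta_i); p_mix is the weight
    of component 1. The marginal of an observed count n with expected
    baseline E is the corresponding negative-binomial mixture.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not (0.0 < self.p_mix < 1.0):
            raise ValueError("p_mix must lie strictly inside (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.p_mix])


CANONICAL_HYPERPARAMS = MgpsHyperParams(*MGPS_START)


@dataclass(frozen=True)
class MgpsFit:
    params: MgpsHyperParams
    loglik: float
    converged: bool
    n_cells: int


def _component_logpmf(
    n: np.ndarray, e: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    # count n | E ~ NegBin(size alpha, prob beta/(beta+E))
    p = beta / (beta + e)
    return sps.nbinom.logpmf(n, alpha, p)


def mixture_loglik(
    theta: Sequence[float], n: np.ndarray, e: np.ndarray
) -> float:
    """Marginal log-likelihood of the negative-binomial mixture."""
    a1, b1, a2, b2, w = theta
    lp1 = np.log(w) + _component_logpmf(n, e, a1, b1)
    lp2 = np.log1p(-w) + _component_logpmf(n, e, a2, b2)
    return float(np.logaddexp(lp1, lp2).sum())


def fit_mgps(
    cells: pd.DataFrame | tuple[np.ndarray, np.ndarray],
    start: Sequence[float] = MGPS_START,
    max_iter: int = 500,
) -> MgpsFit:
    """Fit the mixture prior by marginal maximum likelihood.

    `cells` is either a DataFrame with columns a and E (one row per
    drug-event pair) or a tuple of (count, E) arrays. Box constraints keep
    every parameter >= 1e-6 and the mixing weight inside (0, 1);
    optimization stops when the log-likelihood improvement falls below
    1e-8. Non-convergence returns the best-so-far parameters flagged.
    """
    if isinstance(cells, pd.DataFrame):
        n = cells["a"].to_numpy(dtype=float)
        e = cells["E"].to_numpy(dtype=float)
    else:
        n, e = (np.asarray(x, dtype=float) for x in cells)
    if n.size == 0:
        raise ValueError("no cells to fit")

    def nll(theta: np.ndarray) -> float:
        return -mixture_loglik(theta, n, e)

    bounds = [(1e-6, None)] * 4 + [(1e-6, 1 - 1e-6)]
    res = optimize.minimize(
        nll,
        x0=np.asarray(start, dtype=float),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-8 / max(1.0, abs(mixture_loglik(start, n, e)))},
    )
    params = MgpsHyperParams(*res.x)
    return MgpsFit(params=params, loglik=-float(res.fun), converged=bool(res.success), n_cells=n.size)


def _posterior_mixture(
    a: float, e: float, hyper: MgpsHyperParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior weights, shapes and rates of the two gamma components."""
    shapes = np.array([hyper.alpha1 + a, hyper.alpha2 + a])
    rates = np.array([hyper.beta1 + e, hyper.beta2 + e])
    lw = np.array(
        [
            math.log(hyper.p_mix) + float(_component_logpmf(np.array([a]), np.array([e]), hyper.alpha1, hyper.beta1)[0]),
            math.log1p(-hyper.p_mix) + float(_component_logpmf(np.array([a]), np.array([e]), hyper.alpha2, hyper.beta2)[0]),
        ]
    )
    lw -= special.logsumexp(lw)
    return np.exp(lw), shapes, rates


def posterior_mixture_cdf(
    x: float, weights: np.ndarray, shapes: np.ndarray, rates: np.ndarray
) -> float:
    return float(np.sum(weights * sps.gamma.cdf(x, shapes, scale=1.0 / rates)))


def ebgm(
    table: ContingencyTable | tuple[float, float], hyper: MgpsHyperParams
) -> tuple[float, float]:
    """(EBGM, EB05) for one cell under the fitted mixture prior.

    EBGM = exp E[ln lambda | a] = exp(sum_i Q_i (psi(alpha_i + a) -
    ln(beta_i + E))). EB05 is the 5% quantile of the posterior mixture,
    solved on the mixture CDF to absolute tolerance 1e-8.
    """
    if isinstance(table, ContingencyTable):
        a, e = float(table.a), table.expected
    else:
        a, e = float(table[0]), float(table[1])
    weights, shapes, rates = _posterior_mixture(a, e, hyper)
    log_gm = float(np.sum(weights * (special.digamma(shapes) - np.log(rates))))
    eb = math.exp(log_gm)
    eb05 = posterior_quantile(0.05, weights, shapes, rates)
    return eb, eb05


def posterior_quantile(
    q: float, weights: np.ndarray, shapes: np.ndarray, rates: np.ndarray
) -> float:
    """Quantile of the two-component gamma mixture by root bracketing."""
    comp_q = [float(sps.gamma.ppf(q, shapes[i], scale=1.0 / rates[i])) for i in range(2)]
    lo, hi = min(comp_q), max(comp_q)
    if hi - lo < 1e-10:
        return lo
    # the mixture quantile lies between the component quantiles; widen a
    # hair so brentq sees a strict sign change despite rounding
    lo, hi = lo * (1 - 1e-9), hi * (1 + 1e-9)
    f = lambda x: posterior_mixture_cdf(x, weights, shapes, rates) - q
    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        return lo
    if fhi <= 0.0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# Joint criterion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Joint signal criterion; defaults follow standard pharmacovigilance use."""

    min_cases: int = 3
    ror_rule: bool = True
    prr_rule: bool = True
    ic_rule: bool = True
    ebgm_rule: bool = True
    combine: str = "all"  # "all" | "any"

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.combine not in ("all", "any"):
            raise ValueError("combine must be 'all' or 'any'")


@dataclass
class SignalScores:
    """All statistics for one drug-event pair."""

    event_label: str
    level: str
    n_cases: int
    expected: float
    ror: Estimate
    prr: Estimate
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float
    flags: dict[str, bool] = field(default_factory=dict)


def evaluate_signal(scores: SignalScores, th: Thresholds = Thresholds()) -> SignalScores:
    """Apply the per-algorithm rules and the combined criterion (strict
    inequalities at the stated boundaries; < min_cases is never a signal)."""
    flags = {
        "ror": scores.ror.ci_low > 1.0,
        "prr": scores.prr.value >= 2.0 and scores.chi2 >= 4.0,
        "ic": scores.ic025 > 0.0,
        "ebgm": scores.eb05 > 1.0,
    }
    active = [flags[k] for k, rule in (
        ("ror", th.ror_rule),
        ("prr", th.prr_rule),
        ("ic", th.ic_rule),
        ("ebgm", th.ebgm_rule),
    ) if rule]
    combined = (all(active) if th.combine == "all" else any(active)) if active else False
    if scores.n_cases < th.min_cases:
        combined = False
    flags["combined"] = combined
    scores.flags = flags
    return scores


def score_table(
    table: ContingencyTable,
    hyper: MgpsHyperParams,
    th: Thresholds = Thresholds(),
) -> SignalScores:
    """All four statistics plus flags for one contingency table."""
    ic, ic025 = bcpnn_ic(table)
    eb, eb05 = ebgm(table, hyper)
    scores = SignalScores(
        event_label=table.event_label,
        level=table.level,
        n_cases=table.a,
        expected=table.expected,
        ror=ror(table),
        prr=prr(table),
        chi2=chi_square(table),
        ic=ic,
        ic025=ic025,
        ebgm=eb,
        eb05=eb05,
    )
    return evaluate_signal(scores, th)


def score_tables(
    tables: Sequence[ContingencyTable],
    hyper: MgpsHyperParams,
    th: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Vectorized scoring of many tables; one row per event label.

    Column order mirrors the conventional signal-table layout: event,
    cases, ROR (CI), PRR (CI), chi-square, IC (IC025), EBGM (EB05), flags.
    """
    if not tables:
        return pd.DataFrame(
            columns=[
                "event_label", "level", "n_cases", "E",
                "ror", "ror_low", "ror_high", "prr", "prr_low", "prr_high",
                "chi2", "ic", "ic025", "ebgm", "eb05", "corrected",
                "flag_ror", "flag_prr", "flag_ic", "flag_ebgm", "flag_combined",
            ]
        )
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d
    e_exp = (a + b) * (a + c) / n

    zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    ah, bh, ch, dh = (x + 0.5 * zero for x in (a, b, c, d))

    ror_v = ah * dh / (bh * ch)
    ror_se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    prr_v = (ah / (ah + bh)) / (ch / (ch + dh))
    prr_se = np.sqrt(1 / ah - 1 / (ah + bh) + 1 / ch - 1 / (ch + dh))

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_v = np.where(
            (a + b) * (c + d) * (a + c) * (b + d) > 0,
            n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d)),
            0.0,
        )

    ic_v = np.log2((a + 0.5) / (e_exp + 0.5))
    ic025_v = np.log2(sps.gamma.ppf(0.025, a + 0.5, scale=1.0 / (e_exp + 0.5)))

    eb_v = np.empty_like(a)
    eb05_v = np.empty_like(a)
    for i in range(a.size):
        eb_v[i], eb05_v[i] = ebgm((a[i], e_exp[i]), hyper)

    flag_ror = ror_v * np.exp(-Z95 * ror_se) > 1.0
    flag_prr = (prr_v >= 2.0) & (chi2_v >= 4.0)
    flag_ic = ic025_v > 0.0
    flag_eb = eb05_v > 1.0
    parts = []
    if th.ror_rule:
        parts.append(flag_ror)
    if th.prr_rule:
        parts.append(flag_prr)
    if th.ic_rule:
        parts.append(flag_ic)
    if th.ebgm_rule:
        parts.append(flag_eb)
    if parts:
        stack = np.vstack(parts)
        combined = stack.all(axis=0) if th.combine == "all" else stack.any(axis=0)
    else:
        combined = np.zeros(a.size, dtype=bool)
    combined &= a >= th.min_cases

    return pd.DataFrame(
        {
            "event_label": [t.event_label for t in tables],
            "level": [t.level for t in tables],
            "n_cases": a.astype(int),
            "E": e_exp,
            "ror": ror_v,
            "ror_low": ror_v * np.exp(-Z95 * ror_se),
            "ror_high": ror_v * np.exp(Z95 * ror_se),
            "prr": prr_v,
            "prr_low": prr_v * np.exp(-Z95 * prr_se),
            "prr_high": prr_v * np.exp(Z95 * prr_se),
            "chi2": chi2_v,
            "ic": ic_v,
            "ic025": ic025_v,
            "ebgm": eb_v,
            "eb05": eb05_v,
            "corrected": zero,
            "flag_ror": flag_ror,
            "flag_prr": flag_prr,
            "flag_ic": flag_ic,
            "flag_ebgm": flag_eb,
            "flag_combined": combined,
        }
    )


# ---------------------------------------------------------------------------
# Reconstruction of a 2x2 table from printed summary statistics
# ---------------------------------------------------------------------------


def reconstruct_2x2(
    a: float,
    ror_value: float,
    prr_value: float,
    ror_ci: tuple[float, float],
    z: float = Z95,
) -> tuple[float, float, float, float]:
    """Recover (a, b, c, d) from a printed case count, ROR, PRR and ROR CI.

    Solves the three-equation system ad/bc = ROR,
    [a/(a+b)]/[c/(c+d)] = PRR, and the Woolf variance
    1/a + 1/b + 1/c + 1/d = (ln(hi/lo) / (2z))^2 for b, c, d (continuous
    cells). Useful for internal-consistency checks when only summary
    statistics were published.
    """
    lo, hi = ror_ci
    s2 = (math.log(hi / lo) / (2 * z)) ** 2
    if s2 <= 1 / a:
        raise ValueError("CI too narrow: implied variance below 1/a")

    # starting point from the ROR/PRR ratio identity d(a+b)/(b(c+d)) ~ (a+b)/b
    ratio = ror_value / prr_value
    b0 = a / max(ratio - 1.0, 1e-6)
    rem = s2 - 1 / a - 1 / b0
    c0 = 1 / rem if rem > 0 else 10 * a
    d0 = ror_value * b0 * c0 / a

    def residuals(log_bcd: np.ndarray) -> np.ndarray:
        b, c, d = np.exp(log_bcd)
        return np.array(
            [
                math.log(a * d / (b * c)) - math.log(ror_value),
                math.log((a / (a + b)) / (c / (c + d))) - math.log(prr_value),
                (1 / a + 1 / b + 1 / c + 1 / d) / s2 - 1.0,
            ]
        )

    sol = optimize.fsolve(residuals, np.log([b0, c0, d0]), full_output=True)
    x, info, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"2x2 reconstruction did not converge: {msg}")
    b, c, d = np.exp(x)
    return a, float(b), float(c), float(d)
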