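"""Feasibility and outcome statistics.

Covers every analysis of the deployment study: clinician adherence
(responded / prompted), per-channel response distributions, two-tailed
Fisher's exact test with the conditional maximum-likelihood odds ratio and
exact central confidence interval, Kaplan-Meier product-limit curves with
Greenwood variance and linear-scale 95% confidence intervals, cumulative
incidence, the two-group log-rank test, and Welch's t-test computed from
published summary statistics.

Conventions, stated because they matter for reproducing printed numbers:

* The Fisher odds ratio is the *conditional MLE* with the exact central
  conditional CI — not the sample cross-product ratio.
* The t-test is Welch's (unequal variances) by default, with
  Welch-Satterthwaite degrees of freedom; a pooled-variance option exists.
* Greenwood CIs are on the linear scale (S ± 1.96·SE) clipped to [0, 1];
  a complementary log-log option is provided.
* At tied times, events precede censorings.  All times are integer days;
  six months is 183 days and two years 730 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .alert_workflow import CHANNELS, NO_CONTACT, RESPONDED, AlertCase

__all__ = [
    "TestResult",
    "SurvivalCurve",
    "IncidenceAt",
    "adherence_proportion",
    "channel_distribution",
    "fisher_exact_2x2",
    "km_curve",
    "cumulative_incidence_at",
    "logrank_test",
    "t_from_summary",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    df: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if (
            self.estimate is not None
            and self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low <= self.estimate <= self.ci_high)
        ):
            raise ValueError("confidence interval does not contain the estimate")


def adherence_proportion(cases: Iterable[AlertCase]) -> float:
    """Primary feasibility outcome: responded / prompted clinicians.

    Cases without clinician contact never received a prompt and are
    excluded from the denominator.
    """
    cases = list(cases)
    prompted = sum(c.state != NO_CONTACT for c in cases)
    if prompted == 0:
        raise ValueError("no prompted cases; adherence is undefined")
    responded = sum(c.state == RESPONDED for c in cases)
    return responded / prompted


def channel_distribution(cases: Iterable[AlertCase]) -> dict[str, tuple[int, float]]:
    """Per-channel response count and share of all responses."""
    responded = [c for c in cases if c.state == RESPONDED]
    if not responded:
        raise ValueError("no responded cases")
    out = {}
    for ch in CHANNELS:
        n = sum(c.response_channel == ch for c in responded)
        out[ch] = (n, n / len(responded))
    return out


def personalization_table(cases: Iterable[AlertCase]) -> np.ndarray:
    """2x2 email-response table by alert personalization.

    Rows: alerts using the patient's name vs the anonymised trust
    identifier (prompted cases only); columns: responded to *any email*
    stage vs did not (phone responses count as email non-response, matching
    how the email comparison was reported).
    """
    tab = np.zeros((2, 2), dtype=int)
    for c in cases:
        if c.state == NO_CONTACT:
            continue
        row = 0 if c.personalization == "patient_name" else 1
        email = c.state == RESPONDED and c.response_channel.startswith("EMAIL")
        tab[row, 0 if email else 1] += 1
    return tab


def outreach_table(cases: Iterable[AlertCase]) -> np.ndarray:
    """2x2 overall-response table by borough outreach (prompted cases)."""
    tab = np.zeros((2, 2), dtype=int)
    for c in cases:
        if c.state == NO_CONTACT:
            continue
        row = 0 if c.outreach else 1
        tab[row, 0 if c.state == RESPONDED else 1] += 1
    return tab


def fisher_exact_2x2(table, level: float = 0.95) -> TestResult:
    """Two-tailed Fisher's exact test on a 2x2 table.

    Rows are groups, columns outcome yes/no.  The two-sided p sums the
    hypergeometric point probabilities not exceeding that of the observed
    table; the estimate is the conditional maximum-likelihood odds ratio
    with the exact central conditional CI.  A degenerate outcome margin
    (no successes at all or no failures at all) yields p = 1 with an
    undefined odds ratio, flagged in ``note``.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if tab.sum() == 0:
        raise ValueError("table has no observations")
    a, b = tab[0]
    c, d = tab[1]
    if a + c == 0 or b + d == 0:
        return TestResult(
            statistic=None, p_value=1.0, estimate=None, note="degenerate margin"
        )
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    res = _cmle_odds_ratio(tab, kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return TestResult(
        statistic=None,
        p_value=float(p),
        estimate=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray  # distinct event times, ascending (days)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_total: int
    max_observed_time: float

    def survival_at(self, t_days: float) -> float:
        i = np.searchsorted(self.times, t_days, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_curve(times, event_flags, ci_level: float = 0.95, ci_scale: str = "linear") -> SurvivalCurve:
    """Kaplan-Meier estimate with Greenwood variance.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    Var[S(t)] = S(t)^2 * sum d_i / (n_i (n_i - d_i)) (Greenwood), with the
    convention that events precede censorings at tied times.  The default
    CI is S ± z·SE clipped to [0, 1]; ``ci_scale='loglog'`` gives the
    complementary log-log interval instead.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and event_flags must be equal-length 1-d")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if ci_scale not in ("linear", "loglog"):
        raise ValueError(f"unknown ci_scale {ci_scale!r}")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)

    event_times = np.unique(t[e])
    n = t.size
    surv, var_sum = 1.0, 0.0
    rows = []
    for et in event_times:
        n_i = int((t >= et).sum())  # events first: censored-at-et still at risk
        d_i = int(((t == et) & e).sum())
        surv *= 1.0 - d_i / n_i
        if n_i > d_i:
            var_sum += d_i / (n_i * (n_i - d_i))
            gvar = surv**2 * var_sum
        else:
            gvar = 0.0  # S hit zero; Greenwood variance degenerates
        rows.append((et, n_i, d_i, surv, gvar))

    arr = np.array(rows, dtype=float).reshape(-1, 5)
    surv_v = arr[:, 3]
    gvar_v = arr[:, 4]
    se = np.sqrt(gvar_v)
    if ci_scale == "linear":
        lo = np.clip(surv_v - z * se, 0.0, 1.0)
        hi = np.clip(surv_v + z * se, 0.0, 1.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(surv_v)
            theta = np.where(
                (surv_v > 0) & (surv_v < 1),
                z * se / np.where(surv_v * np.abs(logs) > 0, surv_v * np.abs(logs), 1.0),
                0.0,
            )
            lo = np.where(surv_v > 0, surv_v ** np.exp(theta), 0.0)
            hi = np.where(surv_v > 0, surv_v ** np.exp(-theta), surv_v)
        lo, hi = np.clip(lo, 0, 1), np.clip(hi, 0, 1)
    return SurvivalCurve(
        times=arr[:, 0],
        n_at_risk=arr[:, 1].astype(int),
        n_events=arr[:, 2].astype(int),
        survival=surv_v,
        greenwood_var=gvar_v,
        ci_low=lo,
        ci_high=hi,
        n_total=n,
        max_observed_time=float(t.max()),
    )


@dataclass(frozen=True)
class IncidenceAt:
    t_days: float
    incidence: float
    ci_low: float
    ci_high: float
    n_at_risk: int
    extrapolated: bool = False


def cumulative_incidence_at(
    curve: SurvivalCurve, t_days: float, all_times=None
) -> IncidenceAt:
    """1 - S(t) with the CI mirrored from the survival interval.

    ``all_times`` (the observed times underlying the curve) refines the
    at-risk count at ``t``; without it the count falls back to the at-risk
    count at the last event time <= t.  Past the last observed time the
    last estimate is carried forward and flagged as extrapolated.
    """
    if t_days < 0:
        raise ValueError("t_days must be >= 0")
    extrapolated = t_days > curve.max_observed_time
    i = np.searchsorted(curve.times, t_days, side="right") - 1
    if i < 0:
        s, lo, hi = 1.0, 1.0, 1.0
    else:
        s, lo, hi = curve.survival[i], curve.ci_low[i], curve.ci_high[i]
    if all_times is not None:
        n_risk = int((np.asarray(all_times, dtype=float) >= t_days).sum())
    elif i >= 0:
        n_risk = int(curve.n_at_risk[i] - curve.n_events[i])
    else:
        n_risk = curve.n_total
    return IncidenceAt(
        t_days=float(t_days),
        incidence=1.0 - float(s),
        ci_low=1.0 - float(hi),
        ci_high=1.0 - float(lo),
        n_at_risk=n_risk,
        extrapolated=extrapolated,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test (1 df chi-square).

    Sums observed-minus-expected events in group A over the pooled distinct
    event times, with the hypergeometric variance at each time.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    if not e.any():
        raise ValueError("no events in either group; log-rank is undefined")

    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_j = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d_j = int(((t == et) & e).sum())
        d1 = int(((t == et) & e & g).sum())
        o_minus_e += d1 - d_j * n1 / n_j
        if n_j > 1:
            var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0.0:
        return TestResult(statistic=0.0, p_value=1.0, df=1, note="zero variance")
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p_value=p, df=1)


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = False,
) -> TestResult:
    """Two-sample t-test from summary statistics (Welch by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=mean1 - mean2,
        df=float(df),
    )
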