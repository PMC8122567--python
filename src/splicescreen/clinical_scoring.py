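"""Clinical closed-form scores and PSI + expression risk stratification.

Closed forms:

* H-score for IHC staining: sum of (percent positive area x intensity
  grade) over grades 0-3, range 0-300;
* xenograft tumor volume: length x width^2 / 2 (mm^3 for mm inputs);
* wound-healing relative migration area: (W0 - Wt) / W0 x 100%.

Risk stratification follows the combined-marker design: with the cohort
medians of the target exon's PSI and the splicing factor's expression as
cutoffs, the high-risk group is low PSI AND high expression, the low-risk
group high PSI AND low expression; mixed profiles and median ties are
excluded (the two extreme groups are the only ones defined).  Survival is
compared by Kaplan-Meier curves (product-limit estimator, via lifelines)
and a two-group log-rank test; the log-rank chi-square is computed from
the usual observed-minus-hypergeometric-expected sum over event times,
with either the asymptotic chi-square(1) p-value or a label-permutation
p-value for small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "IhcMeasurement",
    "LogrankResult",
    "h_score",
    "tumor_volume",
    "relative_migration_area",
    "assign_risk_groups",
    "km_estimate",
    "logrank_statistic",
    "logrank_test",
]


@dataclass(frozen=True)
class IhcMeasurement:
    """Staining bins: (PI = percent positive pixel area in [0, 100],
    I = intensity grade in {0, 1, 2, 3})."""

    bins: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for pi, grade in self.bins:
            if not 0 <= pi <= 100:
                raise ValueError("PI must be a percent in [0, 100]")
            if grade not in (0, 1, 2, 3):
                raise ValueError("intensity grade must be in {0, 1, 2, 3}")
            total += pi
        if total > 100 + 1e-9:
            raise ValueError("PI percentages sum above 100")


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    observed_high: float
    expected_high: float
    method: str


def h_score(m: IhcMeasurement) -> float:
    """H-SCORE = sum(PI x I); bounded by 300 on the percent scale."""
    return float(sum(pi * grade for pi, grade in m.bins))


def tumor_volume(length: float, width: float) -> float:
    """length x width^2 / 2; warns and swaps if width exceeds length."""
    if length < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    if width > length:
        warnings.warn("width > length; swapping to the conventional order", stacklevel=2)
        length, width = width, length
    return length * width**2 / 2


def relative_migration_area(w0: float, wt: float) -> float:
    """Wound closure percent: (W0 - Wt) / W0 x 100."""
    if w0 <= 0:
        raise ValueError("initial wounded area W0 must be positive")
    if wt < 0:
        raise ValueError("wounded area must be non-negative")
    return (w0 - wt) / w0 * 100.0


def assign_risk_groups(
    records: pd.DataFrame,
    psi_cutoff: float | None = None,
    expr_cutoff: float | None = None,
) -> pd.DataFrame:
    """Median-cutoff combined risk groups.

    high  <=> psi < psi_cutoff and expression > expr_cutoff
    low   <=> psi > psi_cutoff and expression < expr_cutoff
    everyone else (mixed profiles and exact ties) -> excluded.
    Cutoffs default to the medians of the analyzed cohort (rows with both
    markers present).
    """
    out = records.copy()
    analyzed = out.dropna(subset=["psi", "expression"])
    if len(analyzed) < 2:
        raise ValueError("need >= 2 records with psi and expression")
    if psi_cutoff is None:
        psi_cutoff = float(analyzed["psi"].median())
    if expr_cutoff is None:
        expr_cutoff = float(analyzed["expression"].median())
    psi = out["psi"].to_numpy(float)
    expr = out["expression"].to_numpy(float)
    group = np.full(len(out), "excluded", dtype=object)
    group[(psi < psi_cutoff) & (expr > expr_cutoff)] = "high"
    group[(psi > psi_cutoff) & (expr < expr_cutoff)] = "low"
    group[np.isnan(psi) | np.isnan(expr)] = "excluded"
    out["risk_group"] = group
    if (out["risk_group"] == "excluded").all():
        warnings.warn("all patients excluded (degenerate marker values)", stacklevel=2)
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    Returns the step function as a table (time, at_risk, events, survival);
    right-continuous, starting at S(0) = 1; censored subjects leave the
    risk set without an event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative follow-up times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(float),
            "at_risk": table["at_risk"].to_numpy(int),
            "events": table["observed"].to_numpy(int),
            "censored": table["censored"].to_numpy(int),
            "survival": surv.to_numpy(float),
        }
    )


def logrank_statistic(
    time_a, event_a, time_b, event_b
) -> tuple[float, float, float]:
    """Two-group log-rank chi-square.

    At each distinct event time, the observed events in group A are
    compared with their hypergeometric expectation given the pooled risk
    set; the squared sum of the differences over the summed variance is the
    statistic.  Returns (chi_square, observed_A, expected_A); chi-square is
    NaN when there are no events.
    """
    ta = np.asarray(time_a, float)
    tb = np.asarray(time_b, float)
    ea = np.asarray(event_a, int)
    eb = np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if (ta < 0).any() or (tb < 0).any():
        raise ValueError("negative follow-up times")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return float("nan"), 0.0, 0.0
    o_minus_e = 0.0
    var = 0.0
    observed = 0.0
    expected = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_a).sum()
        e1 = d * n1 / n
        observed += d1
        expected += e1
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return float(chi2), float(observed), float(expected)


def logrank_test(
    group_high: pd.DataFrame,
    group_low: pd.DataFrame,
    method: str = "asymptotic",
    n_permutations: int = 10000,
    seed: int = 0,
) -> LogrankResult:
    """Log-rank comparison of two survival groups (columns time, event).

    ``method="asymptotic"`` uses the chi-square(1) reference;
    ``method="permutation"`` recomputes the statistic under random label
    reshuffles, for small cohorts where the asymptotic reference is
    doubtful.  Zero total events is undefined and returns NaN statistics
    with a warning.
    """
    ta, ea = group_high["time"].to_numpy(float), group_high["event"].to_numpy(int)
    tb, eb = group_low["time"].to_numpy(float), group_low["event"].to_numpy(int)
    chi2, obs, exp = logrank_statistic(ta, ea, tb, eb)
    if np.isnan(chi2):
        warnings.warn("log-rank undefined: no events in either group", stacklevel=2)
        return LogrankResult(float("nan"), float("nan"), obs, exp, method)
    if method == "asymptotic":
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb])
        n_a = ta.size
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(times.size)
            ia = perm[:n_a]
            ib = perm[n_a:]
            stat, _, _ = logrank_statistic(
                times[ia], events[ia], times[ib], events[ib]
            )
            if not np.isnan(stat) and stat >= chi2 - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LogrankResult(chi2, p, obs, exp, method)
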