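"""Differential AS screen: which events does the splicing factor regulate?

The screen tests, per event, whether the inclusion/exclusion read split
differs between knockdown and control (two libraries, no replicates), then
applies the published decision rule — FDR < 0.05 and |dPSI| >= 0.1 — and
calls a direction.  The sign convention is dPSI = PSI_knockdown -
PSI_control, so events the factor ACTIVATES (promotes inclusion of) lose
inclusion under knockdown and have negative dPSI; repressed events have
positive dPSI.

Per-event p-values come from a two-sided Fisher exact test on the 2x2
table [[incl_ctrl, excl_ctrl], [incl_kd, excl_kd]] (exact and
assumption-light for a two-sample design); a binomial likelihood-ratio
test is available as an alternative.  Multiple testing is handled by
Benjamini-Hochberg.

A simple threshold screen for differential expression (|log2FC| and FDR)
is also provided for gene-level matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .psi_quant import DEFAULT_MIN_TOTAL, JunctionCounts, psi_table

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "DifferentialExpressionResult",
    "test_event",
    "binomial_lrt",
    "adjust_fdr",
    "screen_and_classify",
    "screen_events",
    "expression_screen",
    "summarize_screen",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DELTA = 0.1


@dataclass(frozen=True)
class DifferentialResult:
    event_id: str
    psi_control: float
    psi_knockdown: float
    delta_psi: float
    p_value: float
    q_value: float
    direction: str  # activated | repressed | unchanged


@dataclass(frozen=True)
class DifferentialExpressionResult:
    gene: str
    log_fc: float
    p_value: float
    q_value: float
    passes: bool


def test_event(
    counts_control: JunctionCounts, counts_kd: JunctionCounts, method: str = "fisher"
) -> float:
    """Two-sided p-value for a condition effect on the inclusion ratio.

    Returns NaN (and logs the reason) when either condition has zero total
    reads — such events are excluded from the screen.
    """
    table = np.array(
        [
            [counts_control.inclusion, counts_control.exclusion],
            [counts_kd.inclusion, counts_kd.exclusion],
        ]
    )
    if table[0].sum() == 0 or table[1].sum() == 0:
        logger.info(
            "event=%s excluded reason=zero_total_reads", counts_control.event_id
        )
        return float("nan")
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "binomial_lrt":
        return binomial_lrt(table)
    raise ValueError(f"unknown test method {method!r}")


test_event.__test__ = False  # library API named after the operation, not a pytest case


def binomial_lrt(table: np.ndarray) -> float:
    """Binomial likelihood-ratio test of equal inclusion probability in the
    two conditions; asymptotic chi-square with 1 df."""
    table = np.asarray(table, dtype=float)
    n1, n2 = table.sum(axis=1)
    x1, x2 = table[:, 0]
    p1, p2, p0 = x1 / n1, x2 / n2, (x1 + x2) / (n1 + n2)

    def _ll(x, n, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(x > 0, x * np.log(p), 0.0)
            t2 = np.where(n - x > 0, (n - x) * np.log1p(-p), 0.0)
        return t1 + t2

    lr = 2 * (_ll(x1, n1, p1) + _ll(x2, n2, p2) - _ll(x1, n1, p0) - _ll(x2, n2, p0))
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen_and_classify(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> pd.DataFrame:
    """Apply the decision rule to a table with delta_psi and q_value.

    activated  <=> q < alpha and delta_psi <= -min_delta (inclusive)
    repressed  <=> q < alpha and delta_psi >= +min_delta (inclusive)
    otherwise unchanged.
    """
    out = results.copy()
    sig = out["q_value"] < alpha
    direction = np.where(
        sig & (out["delta_psi"] <= -min_delta),
        "activated",
        np.where(sig & (out["delta_psi"] >= min_delta), "repressed", "unchanged"),
    )
    out["direction"] = direction
    return out


def screen_events(
    counts: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_delta: float = DEFAULT_MIN_DELTA,
    method: str = "fisher",
    min_total: int = DEFAULT_MIN_TOTAL,
    control: str = "control",
    knockdown: str = "knockdown",
) -> pd.DataFrame:
    """Full screen over a counts table (replicates pooled within condition).

    Returns one row per testable event: psi in both conditions, dPSI
    (knockdown - control), Fisher p, BH q, direction.  Events with zero
    total reads in either condition are dropped with a logged reason.
    """
    pooled = counts.groupby(["event_id", "condition"], as_index=False)[
        ["inclusion", "exclusion"]
    ].sum()
    wide = pooled.pivot(index="event_id", columns="condition")
    for cond in (control, knockdown):
        if cond not in wide["inclusion"].columns:
            raise ValueError(f"counts table lacks condition {cond!r}")
    ic = wide["inclusion"][control].to_numpy(float)
    ec = wide["exclusion"][control].to_numpy(float)
    ik = wide["inclusion"][knockdown].to_numpy(float)
    ek = wide["exclusion"][knockdown].to_numpy(float)
    testable = (ic + ec > 0) & (ik + ek > 0)
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("screen dropped=%d reason=zero_total_reads", n_dropped)
    event_ids = wide.index.to_numpy()[testable]
    ic, ec, ik, ek = ic[testable], ec[testable], ik[testable], ek[testable]
    if method == "fisher":
        p = np.array(
            [
                stats.fisher_exact([[a, b], [c, d]])[1]
                for a, b, c, d in zip(ic, ec, ik, ek)
            ]
        )
    elif method == "binomial_lrt":
        p = np.array(
            [binomial_lrt([[a, b], [c, d]]) for a, b, c, d in zip(ic, ec, ik, ek)]
        )
    else:
        raise ValueError(f"unknown test method {method!r}")
    psi_c = ic / (ic + ec)
    psi_k = ik / (ik + ek)
    res = pd.DataFrame(
        {
            "event_id": event_ids,
            "psi_control": psi_c,
            "psi_knockdown": psi_k,
            "delta_psi": psi_k - psi_c,
            "p_value": p,
            "q_value": adjust_fdr(p),
            "total_control": (ic + ec).astype(int),
            "total_knockdown": (ik + ek).astype(int),
        }
    )
    return screen_and_classify(res, alpha=alpha, min_delta=min_delta)


def expression_screen(
    expr: pd.DataFrame,
    groups: pd.Series | list,
    log_fc_threshold: float = 1.0,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Threshold screen for differential expression between two groups.

    ``expr`` is genes x samples (non-negative); ``groups`` labels each
    sample with one of exactly two group names.  log2 fold change is taken
    on group means with the configured pseudocount (second group over
    first, in sorted label order); p-values from Welch's t-test on log2
    values, BH-adjusted.  ``passes`` is |log_fc| > threshold and q < alpha.
    Genes constant at zero in both groups get log_fc = 0 and never pass.
    """
    groups = pd.Series(list(groups), index=expr.columns)
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError("expression screen needs exactly two groups")
    a = expr.loc[:, groups[groups == names[0]].index].to_numpy(float)
    b = expr.loc[:, groups[groups == names[1]].index].to_numpy(float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    both_zero = (mean_a == 0) & (mean_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    log_fc = np.where(both_zero, 0.0, log_fc)
    p = stats.ttest_ind(
        np.log2(b + pseudocount + 1e-12),
        np.log2(a + pseudocount + 1e-12),
        axis=1,
        equal_var=False,
    ).pvalue
    p = np.where(np.isnan(p), 1.0, p)
    q = adjust_fdr(p)
    passes = (np.abs(log_fc) > log_fc_threshold) & (q < alpha) & ~both_zero
    return pd.DataFrame(
        {
            "gene": expr.index,
            "log_fc": log_fc,
            "p_value": p,
            "q_value": q,
            "passes": passes,
        }
    ).reset_index(drop=True)


def summarize_screen(
    results: pd.DataFrame, events_meta: pd.DataFrame | None = None
) -> dict:
    """Per-category event counts and regulated fractions (the Fig 3a/3b
    style summary).  ``events_meta`` maps event_id -> category."""
    summary: dict = {"n_tested": int(len(results))}
    counts = results["direction"].value_counts()
    summary["direction_counts"] = {
        d: int(counts.get(d, 0)) for d in ("activated", "repressed", "unchanged")
    }
    n_reg = summary["direction_counts"]["activated"] + summary["direction_counts"]["repressed"]
    summary["regulated_fraction"] = n_reg / len(results) if len(results) else 0.0
    if events_meta is not None or "category" in results.columns:
        if "category" in results.columns:
            merged = results
        else:
            merged = results.merge(
                events_meta[["event_id", "category"]], on="event_id", how="left"
            )
        summary["category_counts"] = (
            merged["category"].value_counts().astype(int).to_dict()
        )
        per_cat = {}
        for cat, grp in merged.groupby("category"):
            reg = grp[grp["direction"] != "unchanged"]
            per_cat[cat] = {
                "activated": int((grp["direction"] == "activated").sum()),
                "repressed": int((grp["direction"] == "repressed").sum()),
                "activated_fraction_of_regulated": (
                    float((reg["direction"] == "activated").mean()) if len(reg) else None
                ),
            }
        summary["per_category"] = per_cat
    return summary
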