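"""Percent-Spliced-In (PSI) quantification from junction read counts.

PSI is the fraction of transcripts including the alternative segment,
estimated from inclusion- and exclusion-supporting junction reads.  Two
estimators are provided: the raw junction ratio inclusion/(inclusion +
exclusion) (default), and an effective-length-normalized form that divides
each count by the number of junction forms supporting it before taking the
ratio — the convention common for skipped exons, where inclusion is
supported by two junctions and exclusion by one.

Events with zero total reads get a missing PSI (never 0/0); events below
the coverage minimum are flagged, not dropped — filtering is the screen's
job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["JunctionCounts", "PsiEstimate", "compute_psi", "psi_table"]

DEFAULT_MIN_TOTAL = 10


@dataclass(frozen=True)
class JunctionCounts:
    """Inclusion/exclusion-supporting read counts for one event in one
    condition.  Effective lengths count the junction forms supporting each
    isoform (>= 1)."""

    event_id: str
    condition: str
    inclusion: int
    exclusion: int
    inclusion_eff_len: int = 1
    exclusion_eff_len: int = 1

    def __post_init__(self) -> None:
        if self.inclusion < 0 or self.exclusion < 0:
            raise ValueError("read counts must be non-negative")
        if self.inclusion_eff_len < 1 or self.exclusion_eff_len < 1:
            raise ValueError("effective lengths must be >= 1")


@dataclass(frozen=True)
class PsiEstimate:
    event_id: str
    condition: str
    psi: float  # NaN when total_reads == 0
    total_reads: int
    low_coverage_flag: bool


def compute_psi(
    counts: JunctionCounts,
    normalize: bool = False,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> PsiEstimate:
    """PSI for one event/condition.

    ``normalize=False``: inclusion / (inclusion + exclusion).
    ``normalize=True``: (inclusion / L_in) / (inclusion / L_in + exclusion / L_ex).
    Zero total reads yield ``psi = NaN`` with the low-coverage flag set.
    """
    total = counts.inclusion + counts.exclusion
    if total == 0:
        psi = math.nan
    elif normalize:
        num = counts.inclusion / counts.inclusion_eff_len
        den = num + counts.exclusion / counts.exclusion_eff_len
        psi = num / den
    else:
        psi = counts.inclusion / total
    return PsiEstimate(
        event_id=counts.event_id,
        condition=counts.condition,
        psi=psi,
        total_reads=total,
        low_coverage_flag=total < min_total,
    )


def psi_table(
    counts: pd.DataFrame,
    normalize: bool = False,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Vectorized PSI over a counts table.

    Expects columns event_id, condition, inclusion, exclusion (optional
    inclusion_eff_len / exclusion_eff_len, replicate).  Replicates are
    pooled by summing counts within (event_id, condition).
    """
    required = {"event_id", "condition", "inclusion", "exclusion"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    agg = {"inclusion": "sum", "exclusion": "sum"}
    for col in ("inclusion_eff_len", "exclusion_eff_len"):
        if col in counts.columns:
            agg[col] = "first"
    pooled = counts.groupby(["event_id", "condition"], as_index=False).agg(agg)
    l_in = pooled.get("inclusion_eff_len", 1)
    l_ex = pooled.get("exclusion_eff_len", 1)
    total = pooled["inclusion"] + pooled["exclusion"]
    if normalize:
        num = pooled["inclusion"] / l_in
        den = num + pooled["exclusion"] / l_ex
    else:
        num, den = pooled["inclusion"], total
    psi = num / den.where(total > 0)  # NaN when no reads
    return pd.DataFrame(
        {
            "event_id": pooled["event_id"],
            "condition": pooled["condition"],
            "psi": psi,
            "total_reads": total,
            "low_coverage_flag": total < min_total,
        }
    )
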