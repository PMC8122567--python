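"""Minigene / RT-PCR splicing quantification.

A minigene reporter expresses a cassette exon with its flanks; on a gel the
inclusion and exclusion isoforms run as separate bands.  The In/Ex index is
the ratio of their intensities; comparing the index between a control lane
and a perturbed lane (splicing-factor knockdown or overexpression) of the
same construct gives a fold-response, and deletion mutants that stop
responding localise the factor's binding element.

Detection-limited zero bands are handled with a pseudo-intensity epsilon
defined relative to the lane's maximum intensity, so the index is always
finite and strictly positive.  No molar correction for amplicon length is
applied by default (band ratios are reported raw); a length-correction
factor can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GelLane",
    "SplicingAssayResult",
    "in_ex_index",
    "classify_response",
    "response_table",
]

DEFAULT_EPSILON_FRAC = 1e-6
DEFAULT_MIN_FOLD = 2.0
CONDITIONS = ("control", "knockdown", "overexpression")


@dataclass(frozen=True)
class GelLane:
    """One gel lane: band intensities in arbitrary densitometry units."""

    sample_id: str
    condition: str
    construct: str
    inclusion_intensity: float
    exclusion_intensity: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.inclusion_intensity < 0 or self.exclusion_intensity < 0:
            raise ValueError("band intensities must be non-negative")
        if self.inclusion_intensity == 0 and self.exclusion_intensity == 0:
            raise ValueError("at least one band intensity must be positive")


@dataclass(frozen=True)
class SplicingAssayResult:
    construct: str
    in_ex_control: float
    in_ex_perturbed: float
    fold_response: float
    responsive: bool


def in_ex_index(
    lane: GelLane,
    epsilon_frac: float = DEFAULT_EPSILON_FRAC,
    length_correction: float = 1.0,
) -> float:
    """(inclusion + eps) / (exclusion + eps) with eps = epsilon_frac x the
    lane's maximum intensity; strictly positive and finite.

    ``length_correction`` multiplies the inclusion intensity (molar
    correction for the longer inclusion amplicon, off by default).
    """
    incl = lane.inclusion_intensity * length_correction
    excl = lane.exclusion_intensity
    eps = epsilon_frac * max(incl, excl)
    return (incl + eps) / (excl + eps)


def classify_response(
    control_lane: GelLane,
    perturbed_lane: GelLane,
    min_fold: float = DEFAULT_MIN_FOLD,
    epsilon_frac: float = DEFAULT_EPSILON_FRAC,
) -> SplicingAssayResult:
    """Fold-response of one construct to a splicing-factor perturbation.

    Oriented so that a construct the factor acts on through the assayed
    exon yields fold >= 1: for overexpression the ratio is
    In/Ex(perturbed) / In/Ex(control); for knockdown it is
    In/Ex(control) / In/Ex(perturbed).  ``responsive`` is fold >= min_fold
    (inclusive).
    """
    if control_lane.construct != perturbed_lane.construct:
        raise ValueError("lanes must carry the same construct")
    if control_lane.condition == perturbed_lane.condition:
        raise ValueError("lanes must differ in condition")
    if control_lane.condition != "control":
        raise ValueError("first lane must be the control condition")
    ctrl = in_ex_index(control_lane, epsilon_frac)
    pert = in_ex_index(perturbed_lane, epsilon_frac)
    if perturbed_lane.condition == "overexpression":
        fold = pert / ctrl
    else:  # knockdown
        fold = ctrl / pert
    return SplicingAssayResult(
        construct=control_lane.construct,
        in_ex_control=ctrl,
        in_ex_perturbed=pert,
        fold_response=fold,
        responsive=fold >= min_fold,
    )


def response_table(
    lanes: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    epsilon_frac: float = DEFAULT_EPSILON_FRAC,
) -> pd.DataFrame:
    """Pair each construct's control lane with its perturbed lane(s) and
    classify responsiveness.  Expects the lanes TSV columns (sample_id,
    condition, construct, inclusion_intensity, exclusion_intensity)."""
    results = []
    for construct, grp in lanes.groupby("construct", sort=True):
        ctrl_rows = grp[grp["condition"] == "control"]
        if ctrl_rows.empty:
            raise ValueError(f"construct {construct!r} has no control lane")
        ctrl = GelLane(**ctrl_rows.iloc[0][
            ["sample_id", "condition", "construct",
             "inclusion_intensity", "exclusion_intensity"]
        ].to_dict())
        for _, row in grp[grp["condition"] != "control"].iterrows():
            pert = GelLane(**row[
                ["sample_id", "condition", "construct",
                 "inclusion_intensity", "exclusion_intensity"]
            ].to_dict())
            r = classify_response(ctrl, pert, min_fold, epsilon_frac)
            results.append(
                {
                    "construct": r.construct,
                    "condition": pert.condition,
                    "in_ex_control": r.in_ex_control,
                    "in_ex_perturbed": r.in_ex_perturbed,
                    "fold_response": r.fold_response,
                    "responsive": r.responsive,
                }
            )
    return pd.DataFrame(results)
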