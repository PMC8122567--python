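"""Synthetic data for the splicing-factor knockdown screen.

Generates every input the downstream stages consume, with the statistical
structure the analysis assumes:

* an AS event catalog across the five categories (SE, RI, A5SS, A3SS, MXE)
  in configurable proportions, allocated by largest-remainder rounding;
* region sequences (upstream constitutive exon, cassette, downstream
  constitutive exon) with a hexamer motif planted position-dependently:
  inside the cassette exon for factor-activated events, inside a flanking
  constitutive exon for factor-repressed events, nowhere for unchanged
  events — and with accidental background copies rejected and re-sampled,
  so the planted signal is the unique ground truth;
* inclusion/exclusion junction read counts under two conditions (control
  and knockdown), Poisson totals with binomial inclusion around the true
  PSI, with the knockdown PSI shifted by the configured dPSI for the
  regulated subset;
* a survival cohort with exponential event times per latent risk group and
  PSI/expression markers placed around the cohort medians so the latent
  group is recoverable by median cutoffs;
* a minigene gel-lane intensity table (full-length construct plus deletion
  mutants) for the In/Ex quantification stage.

All operations are deterministic given the config seed.  Coordinates are
0-based half-open (BED convention); minus-strand events store sense-strand
sequences.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "REGIONS",
    "LABELS",
    "ConfigError",
    "SimulationConfig",
    "SpliceEvent",
    "SyntheticDataset",
    "largest_remainder",
    "generate_event_catalog",
    "assign_labels",
    "draw_true_psi",
    "plant_motifs",
    "simulate_counts",
    "simulate_survival_cohort",
    "simulate_minigene_lanes",
    "simulate_dataset",
]

CATEGORIES = ("SE", "RI", "A5SS", "A3SS", "MXE")
REGIONS = ("upstream_flank", "cassette", "downstream_flank")
LABELS = ("activated", "repressed", "unchanged")

_BASES = np.array(list("ACGT"))
_INTRON_LEN = {"SE": 200, "RI": 0, "A5SS": 150, "A3SS": 150, "MXE": 250}
_EVENT_SPACER = 500

# Fig 3a per-category counts of the screen this generator emulates
_DEFAULT_MIX = (5038 / 6699, 121 / 6699, 354 / 6699, 345 / 6699, 841 / 6699)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Parameters mirror the knockdown experiment: ``true_delta_psi`` is the
    magnitude of the PSI shift induced by knockdown in regulated events
    (activated events lose inclusion, repressed events gain it) and
    ``coverage`` is the mean junction-read total per event and condition.
    """

    n_events: int = 2000
    category_mix: tuple[float, ...] = _DEFAULT_MIX
    frac_activated: float = 0.1
    frac_repressed: float = 0.1
    true_delta_psi: float = 0.4
    coverage: float = 100.0
    planted_motif: str = "GCAGGG"
    repressed_motif: str | None = "GCTGGA"
    exon_len: int = 120
    flank_len: int = 120
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_replicates: int = 1
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ConfigError("n_events must be >= 1")
        mix = tuple(float(m) for m in self.category_mix)
        if len(mix) != len(CATEGORIES):
            raise ConfigError(f"category_mix needs {len(CATEGORIES)} entries")
        if any(m < 0 for m in mix):
            raise ConfigError("category_mix entries must be non-negative")
        if sum(mix) == 0:
            raise ConfigError("category_mix must not sum to zero")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError("category_mix must sum to 1 within 1e-9")
        if not (0 <= self.frac_activated <= 1 and 0 <= self.frac_repressed <= 1):
            raise ConfigError("label fractions must be in [0, 1]")
        if self.frac_activated + self.frac_repressed > 1 + 1e-12:
            raise ConfigError("frac_activated + frac_repressed must be <= 1")
        if not -1 <= self.true_delta_psi <= 1:
            raise ConfigError("true_delta_psi must be in [-1, 1]")
        if self.coverage <= 0:
            raise ConfigError("coverage must be positive")
        for word in filter(None, (self.planted_motif, self.repressed_motif)):
            if len(word) != 6 or set(word) - set("ACGT"):
                raise ConfigError(f"motif {word!r} must be a hexamer over ACGT")
        if self.exon_len < len(self.planted_motif) or self.flank_len < len(
            self.planted_motif
        ):
            raise ConfigError("exon/flank length shorter than the motif width")
        comp = tuple(float(c) for c in self.base_composition)
        if len(comp) != 4 or any(c < 0 for c in comp) or abs(sum(comp) - 1) > 1e-9:
            raise ConfigError("base_composition must be 4 non-negative probs summing to 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion must be positive when given")

    @property
    def motifs(self) -> dict[str, str]:
        """Planted word per regulated direction (repressed falls back to activated)."""
        return {
            "activated": self.planted_motif,
            "repressed": self.repressed_motif or self.planted_motif,
        }


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event: the unit of the screen.

    Intervals are 0-based half-open on the synthetic chromosome; for the RI
    category the ``cassette_region`` is the retained intron and the flanks
    are contiguous with it.
    """

    event_id: str
    category: str
    gene: str
    chrom: str
    strand: str
    upstream_flank: tuple[int, int]
    cassette_region: tuple[int, int]
    downstream_flank: tuple[int, int]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = [self.upstream_flank, self.cassette_region, self.downstream_flank]
        for s, e in ivs:
            if e < s or s < 0:
                raise ValueError("intervals must be non-negative length, start >= 0")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("regions must be ordered and non-overlapping")

    def region(self, name: str) -> tuple[int, int]:
        return {
            "upstream_flank": self.upstream_flank,
            "cassette": self.cassette_region,
            "downstream_flank": self.downstream_flank,
        }[name]


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulated screen produces."""

    config: SimulationConfig
    events: list[SpliceEvent]
    truth: pd.DataFrame  # event_id, label, psi_control, psi_knockdown, motif_region
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if sorted(ids) != sorted(self.truth["event_id"]):
            raise ValueError("every event must have exactly one truth record")
        bad = set(self.truth["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown regulation labels: {bad}")


def largest_remainder(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Allocate ``n`` items to categories by largest-remainder rounding.

    Ties in the remainders are broken by category position, so the
    allocation is deterministic.
    """
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.lexsort((np.arange(len(raw)), -(raw - base)))
    for idx in order[:short]:
        base[idx] += 1
    return base.tolist()


def generate_event_catalog(config: SimulationConfig) -> list[SpliceEvent]:
    """Build ``n_events`` splice events with per-category counts given by
    largest-remainder rounding of ``category_mix``."""
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder(config.n_events, config.category_mix)
    events: list[SpliceEvent] = []
    pos = 0
    i = 0
    for category, n_cat in zip(CATEGORIES, counts):
        gap = _INTRON_LEN[category]
        for _ in range(n_cat):
            up = (pos, pos + config.flank_len)
            cas = (up[1] + gap, up[1] + gap + config.exon_len)
            down = (cas[1] + gap, cas[1] + gap + config.flank_len)
            events.append(
                SpliceEvent(
                    event_id=f"EV{i:06d}",
                    category=category,
                    gene=f"GENE{i:06d}",
                    chrom="chrS",
                    strand="+" if rng.random() < 0.5 else "-",
                    upstream_flank=up,
                    cassette_region=cas,
                    downstream_flank=down,
                )
            )
            pos = down[1] + _EVENT_SPACER
            i += 1
    return events


def assign_labels(
    events: list[SpliceEvent], config: SimulationConfig
) -> dict[str, str]:
    """Assign activated/repressed/unchanged labels in the configured
    fractions (largest-remainder), shuffled deterministically by seed."""
    n = len(events)
    n_act, n_rep, _ = largest_remainder(
        n,
        (
            config.frac_activated,
            config.frac_repressed,
            1 - config.frac_activated - config.frac_repressed,
        ),
    )
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(n)
    labels = {}
    for rank, idx in enumerate(order):
        if rank < n_act:
            lab = "activated"
        elif rank < n_act + n_rep:
            lab = "repressed"
        else:
            lab = "unchanged"
        labels[events[idx].event_id] = lab
    return labels


def draw_true_psi(
    events: list[SpliceEvent], labels: dict[str, str], config: SimulationConfig
) -> pd.DataFrame:
    """Draw true PSI per event and condition.

    Control PSI of regulated events is drawn inside the sub-interval of
    [0.05, 0.95] where the full knockdown shift fits without clipping, so
    the truth labels are exact; any residual overflow is clipped to [0, 1].
    Knockdown PSI is control - dPSI for activated events (the factor
    promoted inclusion) and control + dPSI for repressed events.
    """
    rng = np.random.default_rng(config.seed + 2)
    d = config.true_delta_psi
    rows = []
    for ev in events:
        lab = labels[ev.event_id]
        lo, hi = 0.05, 0.95
        if lab == "activated":
            lo = min(hi, max(lo, d + 0.05))
        elif lab == "repressed":
            hi = max(lo, min(hi, 1 - d - 0.05))
        psi_c = rng.uniform(lo, hi)
        if lab == "activated":
            psi_k = float(np.clip(psi_c - d, 0.0, 1.0))
        elif lab == "repressed":
            psi_k = float(np.clip(psi_c + d, 0.0, 1.0))
        else:
            psi_k = psi_c
        rows.append((ev.event_id, lab, psi_c, psi_k))
    return pd.DataFrame(
        rows, columns=["event_id", "label", "psi_control", "psi_knockdown"]
    )


def _count_hits(seq: str, word: str) -> int:
    return len(re.findall(f"(?={re.escape(word)})", seq))


def _background(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    forbidden: tuple[str, ...],
    max_rounds: int = 200,
) -> str:
    """i.i.d. background sequence with every window spelling a forbidden
    word rejected and re-sampled."""
    seq = rng.choice(_BASES, size=length, p=probs)
    w = len(forbidden[0]) if forbidden else 0
    for _ in range(max_rounds):
        text = "".join(seq)
        hit = -1
        for word in forbidden:
            p = text.find(word)
            if p >= 0 and (hit < 0 or p < hit):
                hit = p
        if hit < 0:
            return text
        seq[hit : hit + w] = rng.choice(_BASES, size=w, p=probs)
    raise ConfigError(
        "could not sample a background free of the planted motif; "
        "base_composition makes the motif unavoidable"
    )


def plant_motifs(
    events: list[SpliceEvent],
    truth_labels: dict[str, str],
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], dict[str, str | None]]:
    """Generate region sequences with the position-dependent planted signal.

    Activated events carry exactly one copy of the activated motif inside
    the cassette exon; repressed events carry exactly one copy of the
    repressed motif inside one flanking constitutive exon (chosen at
    random); unchanged events carry no planted copy anywhere.  Returns
    ``(sequences, placements)`` where ``placements[event_id]`` names the
    region planted into (``None`` for unchanged events).
    """
    rng = np.random.default_rng(config.seed + 3)
    probs = np.asarray(config.base_composition, dtype=float)
    forbidden = tuple(dict.fromkeys(config.motifs.values()))
    lens = {
        "upstream_flank": config.flank_len,
        "cassette": config.exon_len,
        "downstream_flank": config.flank_len,
    }
    sequences: dict[str, dict[str, str]] = {}
    placements: dict[str, str | None] = {}
    for ev in events:
        label = truth_labels[ev.event_id]
        if label == "activated":
            target, word = "cassette", config.motifs["activated"]
        elif label == "repressed":
            target = "upstream_flank" if rng.random() < 0.5 else "downstream_flank"
            word = config.motifs["repressed"]
        else:
            target, word = None, None
        for _ in range(100):
            regions = {
                r: _background(rng, lens[r], probs, forbidden) for r in REGIONS
            }
            if target is not None:
                pos = int(rng.integers(0, lens[target] - len(word) + 1))
                s = regions[target]
                regions[target] = s[:pos] + word + s[pos + len(word) :]
            # insertion may create a second forbidden occurrence across the
            # seam; verify exclusivity and retry if so
            ok = True
            for r in REGIONS:
                for f in forbidden:
                    expect = 1 if (r == target and f == word) else 0
                    if _count_hits(regions[r], f) != expect:
                        ok = False
            if ok:
                break
        else:  # pragma: no cover - 100 failures requires a pathological config
            raise ConfigError(f"could not plant motif exclusively for {ev.event_id}")
        sequences[ev.event_id] = regions
        placements[ev.event_id] = target
    return sequences, placements


def simulate_counts(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw junction counts per event, condition and replicate.

    Totals are Poisson(coverage) (gamma-Poisson when ``dispersion`` is set),
    inclusion reads Binomial(total, true PSI), exclusion the remainder.
    """
    rng = np.random.default_rng(config.seed + 4)
    n = len(truth)
    rows = []
    for cond, psi_col in (("control", "psi_control"), ("knockdown", "psi_knockdown")):
        psis = truth[psi_col].to_numpy(float)
        for rep in range(1, config.n_replicates + 1):
            if config.dispersion is None:
                totals = rng.poisson(config.coverage, size=n)
            else:
                shape = 1.0 / config.dispersion
                lam = rng.gamma(shape, config.coverage / shape, size=n)
                totals = rng.poisson(lam)
            incl = rng.binomial(totals, psis)
            rows.append(
                pd.DataFrame(
                    {
                        "event_id": truth["event_id"].to_numpy(),
                        "condition": cond,
                        "replicate": rep,
                        "inclusion": incl,
                        "exclusion": totals - incl,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_survival_cohort(
    n: int,
    group_hazards: tuple[float, float] = (0.03, 0.01),
    censor_rate: float = 0.2,
    seed: int = 0,
    label_noise: float = 0.0,
) -> pd.DataFrame:
    """Simulate a two-group survival cohort with median-separable markers.

    ``group_hazards`` are (high-risk, low-risk) exponential event rates per
    month.  Censoring is independent exponential with rate chosen so the
    expected censored fraction equals ``censor_rate``.  High-risk patients
    get PSI below / expression above the cohort medians (the Fig-8c-style
    definition: low PSI of the target exon, high factor expression);
    ``label_noise`` flips the marker placement with that probability.
    """
    if n < 2:
        raise ConfigError("cohort size must be >= 2")
    if any(h <= 0 for h in group_hazards):
        raise ConfigError("hazards must be positive")
    if not 0 <= censor_rate < 1:
        raise ConfigError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, size=n)  # 0 = high risk, 1 = low risk
    haz = np.where(group == 0, group_hazards[0], group_hazards[1])
    t_event = rng.exponential(1.0 / haz)
    if censor_rate > 0:
        c_rate = haz * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    marker_group = np.where(rng.random(n) < label_noise, 1 - group, group)
    psi = np.where(
        marker_group == 0, rng.uniform(0.0, 0.45, n), rng.uniform(0.55, 1.0, n)
    )
    expr = np.where(
        marker_group == 0, rng.uniform(0.55, 1.0, n), rng.uniform(0.0, 0.45, n)
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "time": time,
            "event": event,
            "psi": psi,
            "expression": expr,
            "true_group": np.where(group == 0, "high", "low"),
        }
    )


def simulate_minigene_lanes(seed: int = 0, noise_sd: float = 0.05) -> pd.DataFrame:
    """Minigene gel-lane intensities for a full-length reporter and two
    deletion mutants under control vs knockdown.

    The full-length construct and the mutant lacking the second candidate
    element respond to knockdown (the In/Ex index collapses); the mutant
    lacking the primary binding element shows near-zero inclusion in both
    conditions, i.e. no response — the pattern the deletion scan of the
    reporter is designed to reveal.
    """
    true_in_ex = {
        ("FL", "control"): 3.0,
        ("FL", "knockdown"): 0.5,
        ("dE3F1", "control"): 0.12,
        ("dE3F1", "knockdown"): 0.10,
        ("dE3F2", "control"): 2.5,
        ("dE3F2", "knockdown"): 0.6,
    }
    rng = np.random.default_rng(seed)
    rows = []
    for i, ((construct, condition), ratio) in enumerate(true_in_ex.items()):
        excl = 100.0 * float(np.exp(rng.normal(0, noise_sd)))
        incl = ratio * excl * float(np.exp(rng.normal(0, noise_sd)))
        rows.append(
            {
                "sample_id": f"L{i:02d}",
                "condition": condition,
                "construct": construct,
                "inclusion_intensity": round(incl, 3),
                "exclusion_intensity": round(excl, 3),
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: catalog, labels, truth, sequences, counts."""
    events = generate_event_catalog(config)
    labels = assign_labels(events, config)
    truth = draw_true_psi(events, labels, config)
    sequences, placements = plant_motifs(events, labels, config)
    truth = truth.assign(
        motif_region=[placements[e] or "none" for e in truth["event_id"]]
    )
    counts = simulate_counts(truth, config)
    return SyntheticDataset(
        config=config, events=events, truth=truth, sequences=sequences, counts=counts
    )
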