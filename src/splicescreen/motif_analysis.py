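"""Splicing-factor binding-motif discovery from regulated event sets.

The screen's activated and repressed skipped-exon sets are mined for
candidate binding sites in three steps:

1. *Catalog* — enumerate the GA-rich hexamer search space: all 6-mers with
   at least one G, at least one A, and G+A making up at least half the
   positions (the sequence class SR-protein binding sites fall in).
2. *Enrichment* — count overlapping catalog-word occurrences in a
   foreground region set versus a background set (regions of unchanged
   events by default) and rank words by a binomial z-score of the
   foreground frequency against the background rate.
3. *Position* — compare hit densities across the cassette exon and the two
   flanking constitutive exons per event set, calling the preferred region;
   inclusion-promoting factors bind the cassette exon, exclusion-promoting
   binding sits in the flanks.

A PWM is then elicited from the top region's sequences with an in-repo EM
under the one-occurrence-per-sequence model with uniform background
(deterministic initialisation from the top enriched word, no random
restarts).  All scans are on the sense strand; overlapping occurrences
count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .differential_screen import adjust_fdr

__all__ = [
    "KmerCatalog",
    "PositionalProfile",
    "MotifModel",
    "enumerate_filtered_kmers",
    "select_event_sets",
    "count_occurrences",
    "scan_positions",
    "enrichment",
    "positional_preference",
    "elicit_motif",
    "write_meme",
]

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class KmerCatalog:
    """The filtered k-mer search space, sorted lexicographically."""

    k: int
    kmers: tuple[str, ...]
    filter_description: str

    def __contains__(self, word: str) -> bool:
        return word in set(self.kmers)

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass(frozen=True)
class PositionalProfile:
    """Hit densities (per kilobase) per region for each event set, with a
    preference call per set: the region class of maximal density."""

    densities: pd.DataFrame  # columns: event_set, region, hits, kilobases, density
    preference: dict[str, str | None]  # event_set -> cassette | flank | None
    density_ratio: dict[str, float | None]  # top density / runner-up


@dataclass
class MotifModel:
    """Position weight matrix with its elicitation trace.

    ``pwm`` is (width, 4) over A,C,G,T; each row sums to 1.
    """

    width: int
    pwm: np.ndarray
    pseudocount: float
    consensus: str = field(init=False)
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (self.width, 4):
            raise ValueError("pwm must be (width, 4)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        self.consensus = "".join(_ALPHABET[i] for i in self.pwm.argmax(axis=1))


def _is_ga_rich(word: str, min_g: int, min_a: int, min_ga_fraction: float) -> bool:
    g, a = word.count("G"), word.count("A")
    return g >= min_g and a >= min_a and (g + a) / len(word) >= min_ga_fraction


def enumerate_filtered_kmers(
    k: int = 6,
    min_g: int = 1,
    min_a: int = 1,
    min_ga_fraction: float = 0.5,
) -> KmerCatalog:
    """All k-mers with >= min_g G's, >= min_a A's and G+A fraction >=
    min_ga_fraction, sorted lexicographically.

    Infeasible parameter combinations (e.g. min_g + min_a > k) yield an
    empty catalog with a warning rather than an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_g + min_a > k or max(min_g, min_a) / k > 1:
        warnings.warn(
            f"k-mer filter infeasible for k={k}: min_g={min_g}, min_a={min_a}",
            stacklevel=2,
        )
        words: tuple[str, ...] = ()
    else:
        words = tuple(
            w
            for w in ("".join(t) for t in product(_ALPHABET, repeat=k))
            if _is_ga_rich(w, min_g, min_a, min_ga_fraction)
        )
    return KmerCatalog(
        k=k,
        kmers=words,
        filter_description=(
            f"k={k}, >= {min_g} G, >= {min_a} A, G+A fraction >= {min_ga_fraction}"
        ),
    )


def select_event_sets(
    results: pd.DataFrame, n_per_set: int = 50, category: str = "SE"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top regulated skipped-exon events per direction for motif mining.

    Ranking: q ascending, |dPSI| descending, event_id ascending (the same
    evidence ordering used to pick events for validation).  If fewer than
    ``n_per_set`` are available, all are taken with a warning.
    """
    if "category" in results.columns:
        pool = results[results["category"] == category]
    else:
        pool = results
    out = []
    for direction in ("activated", "repressed"):
        sub = pool[pool["direction"] == direction].copy()
        sub["_abs_delta"] = sub["delta_psi"].abs()
        sub = sub.sort_values(
            ["q_value", "_abs_delta", "event_id"], ascending=[True, False, True]
        ).drop(columns="_abs_delta")
        if len(sub) < n_per_set:
            warnings.warn(
                f"only {len(sub)} {direction} {category} events available "
                f"(requested {n_per_set})",
                stacklevel=2,
            )
        out.append(sub.head(n_per_set).reset_index(drop=True))
    return out[0], out[1]


def _windows(seq: str, k: int) -> int:
    return max(len(seq) - k + 1, 0)


def count_occurrences(
    kmers: KmerCatalog | tuple[str, ...],
    sequences: list[str] | dict[str, str],
    overlapping: bool = True,
) -> pd.DataFrame:
    """Sliding-window occurrence counts per k-mer over a sequence set.

    Overlapping occurrences count by default.  Windows containing a
    non-ACGT character (e.g. N) are skipped; sequences shorter than k
    contribute zero counts and zero scanned length.  Returns per-kmer
    counts plus density per kilobase of scanned windows.
    """
    words = tuple(kmers.kmers) if isinstance(kmers, KmerCatalog) else tuple(kmers)
    if not words:
        return pd.DataFrame(columns=["kmer", "count", "kilobases", "density_per_kb"])
    k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("all k-mers must share one width")
    word_set = set(words)
    counts = dict.fromkeys(words, 0)
    n_windows = 0
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    for seq in seqs:
        seq = seq.upper()
        step = 1 if overlapping else k
        i = 0
        while i <= len(seq) - k:
            w = seq[i : i + k]
            if set(w) <= set(_ALPHABET):
                n_windows += 1
                if w in word_set:
                    counts[w] += 1
            i += step
    kb = n_windows / 1000.0
    return pd.DataFrame(
        {
            "kmer": words,
            "count": [counts[w] for w in words],
            "kilobases": kb,
            "density_per_kb": [counts[w] / kb if kb > 0 else 0.0 for w in words],
        }
    )


def scan_positions(
    kmers: KmerCatalog | tuple[str, ...], sequences: dict[str, str]
) -> pd.DataFrame:
    """Hit locations (sequence id, 0-based start, kmer) for BED export."""
    words = tuple(kmers.kmers) if isinstance(kmers, KmerCatalog) else tuple(kmers)
    word_set = set(words)
    if not words:
        return pd.DataFrame(columns=["seq_id", "start", "end", "kmer"])
    k = len(words[0])
    rows = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        for i in range(_windows(seq, k)):
            w = seq[i : i + k]
            if w in word_set:
                rows.append({"seq_id": seq_id, "start": i, "end": i + k, "kmer": w})
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "kmer"])


def enrichment(
    foreground: list[str],
    background: list[str],
    kmers: KmerCatalog | tuple[str, ...],
    overlapping: bool = True,
) -> pd.DataFrame:
    """Per-kmer binomial z of the foreground occurrence rate vs background.

    The null rate per window is the background occurrence frequency; words
    absent from the background get a pseudo-rate of one occurrence over the
    total background windows.  Two-sided normal p, BH q, ranked by z
    descending.  Frequencies are also reported per kilobase.
    """
    if not foreground or not background:
        raise ValueError("foreground and background sets must be non-empty")
    fg = count_occurrences(kmers, foreground, overlapping=overlapping)
    bg = count_occurrences(kmers, background, overlapping=overlapping)
    n_fg = fg["kilobases"].iloc[0] * 1000.0 if len(fg) else 0.0
    n_bg = bg["kilobases"].iloc[0] * 1000.0 if len(bg) else 0.0
    if n_fg == 0 or n_bg == 0:
        raise ValueError("no scannable windows in foreground or background")
    merged = fg.merge(bg, on="kmer", suffixes=("_fg", "_bg"))
    p0 = merged["count_bg"].to_numpy(float) / n_bg
    p0 = np.where(p0 == 0, 1.0 / n_bg, p0)  # pseudo-frequency for unseen words
    x = merged["count_fg"].to_numpy(float)
    mu = n_fg * p0
    sd = np.sqrt(n_fg * p0 * (1 - p0))
    z = (x - mu) / sd
    # a word absent from both sets carries no evidence either way
    z = np.where((x == 0) & (merged["count_bg"].to_numpy(float) == 0), 0.0, z)
    from scipy import stats as _st

    p = 2 * _st.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "kmer": merged["kmer"],
            "foreground_freq": merged["density_per_kb_fg"],
            "background_freq": merged["density_per_kb_bg"],
            "z_score": z,
            "p_value": p,
            "q_value": adjust_fdr(p),
        }
    )
    return out.sort_values(
        ["z_score", "kmer"], ascending=[False, True]
    ).reset_index(drop=True)


def positional_preference(
    activated_regions: dict[str, list[str]],
    repressed_regions: dict[str, list[str]],
    kmers: KmerCatalog | tuple[str, ...],
) -> PositionalProfile:
    """Catalog-hit density per region for the two event sets, with a
    cassette-vs-flank preference call per set.

    The preference is "cassette" when the cassette exon has the maximal
    density, "flank" when either constitutive flank does, and None
    (flagged) when no catalog word hits at all.
    """
    rows = []
    preference: dict[str, str | None] = {}
    ratio: dict[str, float | None] = {}
    for set_name, regions in (
        ("activated", activated_regions),
        ("repressed", repressed_regions),
    ):
        dens = {}
        for region, seqs in regions.items():
            tab = count_occurrences(kmers, seqs)
            hits = int(tab["count"].sum())
            kb = float(tab["kilobases"].iloc[0]) if len(tab) else 0.0
            dens[region] = hits / kb if kb > 0 else 0.0
            rows.append(
                {
                    "event_set": set_name,
                    "region": region,
                    "hits": hits,
                    "kilobases": kb,
                    "density_per_kb": dens[region],
                }
            )
        if not dens or max(dens.values()) == 0:
            preference[set_name] = None
            ratio[set_name] = None
            continue
        ordered = sorted(dens.items(), key=lambda kv: -kv[1])
        top_region, top = ordered[0]
        runner = ordered[1][1] if len(ordered) > 1 else 0.0
        preference[set_name] = "cassette" if top_region == "cassette" else "flank"
        ratio[set_name] = top / runner if runner > 0 else float("inf")
    return PositionalProfile(
        densities=pd.DataFrame(rows), preference=preference, density_ratio=ratio
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in seq], dtype=int)


def elicit_motif(
    sequences: list[str],
    width: int = 6,
    init_kmer: str | None = None,
    pseudocount: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MotifModel:
    """EM motif elicitation under a one-occurrence-per-sequence model.

    Each sequence is assumed to contain exactly one motif occurrence at a
    uniformly distributed start, with all other positions from a uniform
    background.  The E-step computes the posterior over start positions per
    sequence; the M-step re-estimates the PWM from posterior-weighted base
    counts plus the pseudocount.  Iteration stops at ``max_iter`` or when
    the log-likelihood improves by less than ``tol``; the trace is
    guaranteed non-decreasing (standard EM monotonicity).

    Initialisation is deterministic: from ``init_kmer`` when given (base
    probability 0.7 at the seed letter), otherwise from the most frequent
    width-mer in the sequences.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    for i, s in enumerate(sequences):
        if len(s) < width:
            raise ValueError(
                f"sequence #{i} ({s[:12]!r}...) is shorter than width {width}"
            )
    seqs = [_encode(s.upper()) for s in sequences]

    if init_kmer is None:
        from collections import Counter

        cnt: Counter[str] = Counter()
        for s in sequences:
            s = s.upper()
            for j in range(len(s) - width + 1):
                cnt[s[j : j + width]] += 1
        init_kmer = min(cnt, key=lambda w: (-cnt[w], w))
    if len(init_kmer) != width:
        raise ValueError("init_kmer length must equal width")

    pwm = np.full((width, 4), 0.1)
    for i, b in enumerate(init_kmer):
        pwm[i, _BASE_INDEX[b]] = 0.7

    bg = 0.25
    loglik_trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: posterior over start positions under the current PWM
        post = []
        loglik = 0.0
        log_pwm = np.log(pwm)
        for s in seqs:
            m = len(s) - width + 1
            # log-ratio of motif vs background over each window
            scores = np.empty(m)
            for j in range(m):
                scores[j] = log_pwm[np.arange(width), s[j : j + width]].sum()
            scores -= width * np.log(bg)  # window likelihood ratio
            # per-sequence likelihood: uniform prior over starts, background
            # elsewhere (constant across starts, kept for an honest loglik)
            base = len(s) * np.log(bg) - np.log(m)
            mx = scores.max()
            lse = mx + np.log(np.exp(scores - mx).sum())
            loglik += base + lse
            g = np.exp(scores - lse)
            post.append(g)
        loglik_trace.append(loglik)
        # M-step: posterior-weighted base counts
        counts = np.full((width, 4), pseudocount)
        for s, g in zip(seqs, post):
            for j, w in enumerate(g):
                counts[np.arange(width), s[j : j + width]] += w
        pwm = counts / counts.sum(axis=1, keepdims=True)
        if loglik - prev < tol and np.isfinite(prev):
            break
        prev = loglik
    model = MotifModel(width=width, pwm=pwm, pseudocount=pseudocount)
    model.loglik_trace = loglik_trace
    return model


def write_meme(model: MotifModel, path, name: str = "MOTIF1") -> None:
    """Minimal MEME text format: version line, alphabet, letter-probability
    matrix."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name} {model.consensus}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {model.width} nsites= 1 E= 0\n"
        )
        for row in model.pwm:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
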