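"""Independent oracles used by the tests.

These deliberately avoid the package's code paths: the Fisher oracle sums
the hypergeometric pmf directly from log-factorials, the k-mer oracle
re-derives the GA-rich predicate from letter counts, and the k-mer counter
uses regex lookahead.
"""

from __future__ import annotations

import re
from itertools import product

import numpy as np
from scipy.special import gammaln


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by exhaustive enumeration over all tables
    with the observed margins (method of small p-values)."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    p = np.exp(logp)
    pa = p[ks == a][0]
    return float(p[p <= pa * (1 + 1e-7)].sum())


def fisher_all_tables(r1: int, r2: int) -> dict[tuple[int, int], float]:
    """Two-sided p for every table with row sums (r1, r2), keyed (a, c)."""
    out: dict[tuple[int, int], float] = {}
    n = r1 + r2
    for c1 in range(n + 1):
        lo, hi = max(0, c1 - r2), min(r1, c1)
        ks = np.arange(lo, hi + 1)
        logp = (
            gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
            + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )
        p = np.exp(logp)
        for a, pa in zip(ks, p):
            out[(int(a), int(c1 - a))] = float(p[p <= pa * (1 + 1e-7)].sum())
    return out


def ga_rich_kmers(k: int, min_g: int, min_a: int, min_ga_fraction: float) -> set[str]:
    """Brute-force enumeration of the GA-rich k-mer class from letter
    counts (2*(G+A) >= k for the default half fraction, handled exactly
    with integer arithmetic)."""
    words = set()
    for tup in product("ACGT", repeat=k):
        g = sum(1 for x in tup if x == "G")
        a = sum(1 for x in tup if x == "A")
        if g >= min_g and a >= min_a and (g + a) >= min_ga_fraction * k:
            words.add("".join(tup))
    return words


def regex_count(word: str, sequences) -> int:
    """Overlapping occurrence count via regex lookahead."""
    pat = re.compile(f"(?={re.escape(word)})")
    return sum(len(pat.findall(s.upper())) for s in sequences)


def km_by_hand(times, events):
    """Product-limit estimator computed directly from its definition.
    Returns {event_time: survival_just_after}."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / n_at_risk
        out[float(t)] = s
    return out
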