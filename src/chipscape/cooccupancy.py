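"""Gap-tolerant co-occupancy counting and hypergeometric enrichment.

The statistical population is a reference peak set (the "universe", e.g.
the H3K27ac-high distal peaks of the main factor). For a factor pair (A, B)
each universe peak is marked 0/1 by each factor — a universe peak counts
once no matter how many factor peaks hit it — and the number of doubly
marked peaks is tested against the hypergeometric null of independent
sampling without replacement:

    P[X >= k],  X ~ Hypergeometric(N, K, n)

with N universe peaks, K marked by A, n marked by B, k marked by both.
Benjamini-Hochberg FDR is applied across the requested pair list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .core import PeakSet
from .intervals import intersect_sets

# below this population size the upper tail is computed in exact rational
# arithmetic; above it, by log-space summation of the pmf
_EXACT_N_MAX = 10_000


def mark_universe(
    universe: PeakSet, factor: PeakSet, max_gap: int = 200
) -> np.ndarray:
    """Boolean vector over universe peaks: True where the peak overlaps, or
    lies within ``max_gap`` bp of, at least one factor peak."""
    marks = np.zeros(len(universe), dtype=bool)
    if max_gap == 0:
        pairs = intersect_sets(universe, factor, min_overlap=1, max_gap=0)
    else:
        pairs = intersect_sets(universe, factor, max_gap=max_gap)
    for i, _ in pairs:
        marks[i] = True
    return marks


def _validate_margins(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"margins out of range: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")


def hypergeometric_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P[X >= k] for X ~ Hypergeometric(N, K, n).

    Exact rational arithmetic for small populations; log-space summation of
    pmf terms otherwise, so deep tails keep full relative precision.
    """
    _validate_margins(N, K, n, k)
    if k == 0:
        return 1.0
    if N <= _EXACT_N_MAX:
        return _upper_exact(N, K, n, k)
    return _upper_log(N, K, n, k)


def _upper_exact(N: int, K: int, n: int, k: int) -> float:
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return float(Fraction(acc, total))


def _upper_log(N: int, K: int, n: int, k: int) -> float:
    ks = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(ks, N, K, n)
    return float(np.exp(logsumexp(logp)))


def hypergeometric_lower(N: int, K: int, n: int, k: int) -> float:
    """Lower-tail P[X <= k] (depletion direction, exposed as an option)."""
    _validate_margins(N, K, n, k)
    if N <= _EXACT_N_MAX:
        total = math.comb(N, n)
        acc = 0
        for j in range(max(0, K + n - N), k + 1):
            acc += math.comb(K, j) * math.comb(N - K, n - j)
        return float(Fraction(acc, total))
    return float(stats.hypergeom.cdf(k, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass
class CooccupancyResult:
    pair_label: str
    n_universe: int
    n_a: int
    n_b: int
    n_both: int
    p_value: float
    q_value: float = math.nan

    def as_dict(self) -> dict:
        return {
            "pair": self.pair_label,
            "N": self.n_universe,
            "K": self.n_a,
            "n": self.n_b,
            "k": self.n_both,
            "p_value": self.p_value,
            "q_value": self.q_value,
        }


def pairwise_table(
    universe: PeakSet,
    factors: Mapping[str, PeakSet],
    pairs: Sequence[tuple[str, str]],
    max_gap: int = 200,
    alternative: str = "greater",
) -> list[CooccupancyResult]:
    """Co-occupancy enrichment over the universe for each requested factor
    pair, with BH-FDR across the request list.

    ``alternative="greater"`` tests enrichment (upper tail, the default);
    ``"less"`` tests depletion.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    for label_a, label_b in pairs:
        for lab in (label_a, label_b):
            if lab not in factors:
                raise KeyError(f"unknown factor label {lab!r}")
    marks = {
        lab: mark_universe(universe, factors[lab], max_gap=max_gap)
        for lab in {l for pair in pairs for l in pair}
    }
    N = len(universe)
    results = []
    for label_a, label_b in pairs:
        ma, mb = marks[label_a], marks[label_b]
        K, n, k = int(ma.sum()), int(mb.sum()), int((ma & mb).sum())
        if alternative == "greater":
            p = hypergeometric_upper(N, K, n, k)
        else:
            p = hypergeometric_lower(N, K, n, k)
        results.append(
            CooccupancyResult(f"{label_a}/{label_b}", N, K, n, k, p)
        )
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
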