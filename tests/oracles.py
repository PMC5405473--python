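"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit pair loops, per-base
boolean arrays, full hypergeometric enumeration, sort-and-count tails.
None of it shares code with the package paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def pairwise_differences_mean(haplotypes: np.ndarray) -> float:
    """Average Hamming distance over all C(n,2) rows of a (n, sites) matrix."""
    n = haplotypes.shape[0]
    total = sum(int(np.sum(haplotypes[i] != haplotypes[j]))
                for i, j in combinations(range(n), 2))
    return total / (n * (n - 1) / 2)


def tajimas_d_direct(S: int, k_hat: float, n: int) -> float:
    """Full-precision evaluation of the D formula chain, written out."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def per_base_callable(length: int, masked: list[tuple[int, int]],
                      missing: list[int]) -> int:
    """Callable bases by filling an explicit boolean array."""
    ok = np.ones(length, dtype=bool)
    for s, e in masked:
        ok[max(0, s):min(length, e)] = False
    for p in missing:
        if 0 <= p < length:
            ok[p] = False
    return int(ok.sum())


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing point probabilities <= observed.

    Enumerates every table with the observed margins using exact
    log-factorial arithmetic (minimum-likelihood convention).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lf = [math.lgamma(i + 1) for i in range(n + 1)]

    def log_p(x):  # table (x, r1-x; c1-x, r2-c1+x)
        return (lf[r1] + lf[r2] + lf[c1] + lf[n - c1] - lf[n]
                - lf[x] - lf[r1 - x] - lf[c1 - x] - lf[r2 - c1 + x])

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


def tail_cut_sort_and_count(values: np.ndarray, tail_fraction: float):
    """Sort-and-count upper-tail oracle with block tie handling.

    Returns (threshold or None, flagged_count) for the conservative
    (never exceed the tail) policy.
    """
    x = np.sort(np.asarray(values, dtype=float))[::-1]
    n = len(x)
    k_max = int(math.floor(tail_fraction * n))
    best = None
    for k in range(k_max, 0, -1):
        v = x[k - 1]
        count = int(np.sum(x >= v))
        if count <= k_max:
            best = (float(v), count)
            break
    if best is None:
        return None, 0
    return best
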