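"""Independent brute-force oracles used across the test suite.

These deliberately share no code with the implementation: the DFT is the
literal O(N^2) sum, the Mann-Whitney p comes from full enumeration of
group assignments, and the Fisher p from exact rational hypergeometric
enumeration.
"""

from __future__ import annotations

import cmath
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def dft_direct(series) -> np.ndarray:
    """Fourier coefficients for n = 1..floor(N/2) by the direct double sum."""
    x = list(series)
    n_points = len(x)
    out = []
    for n in range(1, n_points // 2 + 1):
        total = 0j
        for m, value in enumerate(x):
            total += value * cmath.exp(-2j * cmath.pi * n * m / n_points)
        out.append(total)
    return np.asarray(out)


def spectrum_direct(series) -> np.ndarray:
    return np.abs(dft_direct(series)) ** 2


def mwu_enumeration_p(group_a, group_b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Tie-free data only.  Two-sided p is the null probability of a U at
    least as far from its mean n1*n2/2 as the observed one.
    """
    a = list(group_a)
    b = list(group_b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(a), len(b)
    rank_of = {v: r + 1 for r, v in enumerate(pooled)}

    def u_stat(values):
        rank_sum = sum(rank_of[v] for v in values)
        return rank_sum - n1 * (n1 + 1) / 2

    u_obs = u_stat(a)
    mean = n1 * n2 / 2
    dev = abs(u_obs - mean)
    hits = 0
    total = 0
    for subset in combinations(pooled, n1):
        total += 1
        if abs(u_stat(subset) - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


def fisher_enumeration_p(table) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(n - r1, c1 - k), comb(n, c1))

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    probs = {k: pmf(k) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
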