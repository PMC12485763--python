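"""Independent oracle implementations used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle uses
exact integer hypergeometric enumeration, the BH oracle a quadratic
definition-level scan, and the r2 oracle the textbook Pearson formula via
numpy.corrcoef.
"""

import math
from fractions import Fraction

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational, by enumerating all tables
    with the observed margins and summing those no more probable."""
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(r1 + r2, c1)
    num = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= w_obs:
            num += w
    return Fraction(num, total)


def bh_naive(p_values) -> np.ndarray:
    """Definition-level BH: q_i = min over j with p_j >= p_i (by rank) of
    p_(j) * m / j, capped at 1. Quadratic scan, no shared code with the
    implementation."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i in range(m):
        best = 1.0
        for rank_j in range(rank_i, m):
            cand = p[order[rank_j]] * m / (rank_j + 1)
            if cand < best:
                best = cand
        q[order[rank_i]] = best
    return q


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation via numpy's correlation matrix."""
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1] ** 2)
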