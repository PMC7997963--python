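"""Independent brute-force oracles used to pin expected test values.

Everything here is deliberately naive (exact rational enumeration, closed
forms, hand computation) and never calls the code paths under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, exp, factorial, log

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the point probabilities of every table with the same margins whose
    probability does not exceed the observed table's (point-probability rule),
    computed in exact rational arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p by enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    total = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        if c1 - x <= r2:
            total += Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    return float(total)


def wilcoxon_two_sided_oracle(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group splits.

    Valid for tie-free data. Uses the 2*min(P(U<=u), P(U>=u)) convention,
    capped at 1.
    """
    values = list(x) + list(y)
    assert len(set(values)) == len(values), "oracle assumes no ties"
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(values)), n_x):
        chosen = [values[i] for i in combo]
        rest = [values[i] for i in range(len(values)) if i not in combo]
        us.append(sum(1 for xi in chosen for yj in rest if xi > yj))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, written out longhand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running_min = min(running_min, p[i] * m / (rank_pos + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def chi2_upper_tail_even_df(x: float, df: int) -> float:
    """Closed-form chi-square upper tail for even df:
    P(X > x) = exp(-x/2) * sum_{j=0}^{k-1} (x/2)^j / j!, with k = df/2."""
    assert df % 2 == 0 and df > 0
    k = df // 2
    half = x / 2.0
    return exp(-half) * sum(half**j / factorial(j) for j in range(k))


def cerno_oracle(ranks, n_total: int) -> float:
    """F = -2 sum ln(r_i/N_tot), via math.log one term at a time."""
    return -2.0 * sum(log(r / n_total) for r in ranks)


def rank_ascending_oracle(values) -> list[float]:
    """Average ascending ranks by pairwise counting (O(n^2), no sorting)."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out
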