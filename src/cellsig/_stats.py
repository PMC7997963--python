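"""Shared statistical primitives: 2x2 Fisher exact test, BH adjustment, z-scores.

A single Fisher routine is used by both the condition-enrichment test and the
cluster-composition test so the two agree bit-for-bit on identical tables.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_ALTERNATIVES = ("two-sided", "less", "greater")


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact hypergeometric test on a 2x2 contingency table.

    Returns ``(odds_ratio, p)``. The odds ratio is the sample odds ratio
    a*d / (b*c); a zero in b or c with nonzero numerator gives ``inf``, and a
    zero numerator and denominator gives ``nan``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    (a, b), (c, d) = t
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    else:
        odds = np.nan if num == 0 else np.inf
    p = float(stats.fisher_exact(t, alternative=alternative).pvalue)
    return float(odds), min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to <= 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def zscore_vector(x) -> np.ndarray:
    """Standardize a vector with the sample (n-1) standard deviation.

    Constant vectors map to all zeros rather than dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd
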