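"""Rank-test and multiple-testing helpers shared by the marker and bimodality modules."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_rank_sum", "bh_adjust", "bonferroni_adjust"]

_EXACT_MAX = 25


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of x vs y.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``. The
    null distribution is enumerated exactly when both groups have <= 25
    observations and the pooled sample is tie-free; otherwise the tie-corrected
    normal approximation (no continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    uniq = np.unique(pooled)
    if len(uniq) == 1:  # all observations tied: no evidence either way
        return float(len(x) * len(y) / 2.0), 1.0
    tie_free = len(uniq) == len(pooled)
    if len(x) <= _EXACT_MAX and len(y) <= _EXACT_MAX and tie_free:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment: q_i = min_{j>=i} (p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment with multiplier m (default: the family size)."""
    p = np.asarray(p, dtype=float)
    mult = len(p) if m is None else m
    return np.minimum(p * mult, 1.0)
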