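"""Decile analysis of a bimodal transcript distribution.

For a gene like *Tph2* whose per-cell transcript counts form two modes, cells
are partitioned into deciles of the count distribution and the mixing of
protein-positive and protein-negative cells is quantified per decile with the
intermixing index 1 - |2f - 1| (f = fraction positive): 0 for a pure decile,
1 for a perfectly mixed one. The deciles where intermixing peaks are the
"transition zone" between the modes. Grouped comparisons use two-sided
Wilcoxon rank-sum tests with Benjamini-Hochberg correction across the declared
comparison family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger("seroclust")

__all__ = [
    "DecileAssignment",
    "decile_partition",
    "intermixing_by_decile",
    "group_test",
]


@dataclass
class DecileAssignment:
    """Per-cell decile index (1-10) of a value distribution.

    Values are stably sorted (ties broken by input order) and split into ten
    near-equal blocks; when n is not divisible by 10 the *lowest* deciles take
    the extra cells.
    """

    values: np.ndarray
    decile: np.ndarray
    degenerate: bool = False  # all values identical


def decile_partition(values) -> DecileAssignment:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 10:
        raise ValueError(f"need at least 10 values, got {n}")
    degenerate = bool(np.all(values == values[0]))
    if degenerate:
        logger.warning("all values identical; deciles follow input order")

    order = np.argsort(values, kind="stable")
    base, extra = divmod(n, 10)
    sizes = np.array([base + 1 if i < extra else base for i in range(10)])
    decile_of_rank = np.repeat(np.arange(1, 11), sizes)
    decile = np.empty(n, dtype=int)
    decile[order] = decile_of_rank
    return DecileAssignment(values=values, decile=decile, degenerate=degenerate)


def intermixing_by_decile(assignment: DecileAssignment, positive) -> pd.DataFrame:
    """Per-decile positive fraction and intermixing index 1 - |2f - 1|."""
    positive = np.asarray(positive, dtype=bool)
    if len(positive) != len(assignment.decile):
        raise ValueError("positive must be defined for every cell")
    rows = []
    for d in range(1, 11):
        mask = assignment.decile == d
        f = float(positive[mask].mean()) if mask.any() else np.nan
        rows.append(
            {
                "decile": d,
                "n": int(mask.sum()),
                "fraction_positive": f,
                "intermixing": 1.0 - abs(2.0 * f - 1.0) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def group_test(values, groups, comparisons) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests for named group pairs, BH-corrected
    across the comparison family.

    ``comparisons`` is a list of (group_a, group_b) names; each must be
    non-empty in ``groups``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")

    rows = []
    for a, b in comparisons:
        xa = values[groups == a]
        xb = values[groups == b]
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"comparison ({a!r}, {b!r}) references an empty group")
        u, p = wilcoxon_rank_sum(xa, xb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "statistic": u,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out
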