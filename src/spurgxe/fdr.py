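"""Benjamini-Hochberg and two-level hierarchical FDR control.

The hierarchical procedure organizes hypotheses into a tree: the top level
holds one omnibus likelihood-ratio hypothesis per filter (f families), and
the children of each omnibus hypothesis are the per-interaction tests of
its test-stage model.  BH is run at level q within each level, and child
families are only opened for parents rejected at the top.  The realized
level-specific FDR of this scheme is bounded by approximately

    q * delta_star * (d + f) / (d + 1)

where d is the number of child discoveries and delta_star ~= 1; e.g. with
f=2 filter families, d=4 discoveries and q=0.1 the bound is
0.1 * (2+4) / (4+1) = 0.12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "hierarchical_fdr", "effective_fdr_level", "HierarchyResult"]


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values, in input order.

    Missing entries (NaN) are excluded from the family size m and returned
    as NaN.  Values outside [0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class HierarchyResult:
    parent_pvalues: np.ndarray
    parent_qvalues: np.ndarray
    rejected_parents: np.ndarray          # boolean mask, length f
    child_qvalues: list[np.ndarray | None]  # None for non-rejected parents
    child_rejected: list[np.ndarray | None]
    discoveries: int                      # d = total child rejections
    effective_level: float
    q: float

    @property
    def n_families(self) -> int:
        return len(self.parent_pvalues)


def effective_fdr_level(q: float, f: int, d: int, delta_star: float = 1.0) -> float:
    """Level-specific FDR bound q * delta_star * (d + f) / (d + 1)."""
    if f < 1:
        raise ValueError("f must be >= 1")
    if d < 0:
        raise ValueError("d must be >= 0")
    return q * delta_star * (d + f) / (d + 1)


def hierarchical_fdr(
    parent_pvalues,
    children,
    q: float = 0.1,
    delta_star: float = 1.0,
) -> HierarchyResult:
    """Two-level hierarchical BH.

    Parameters
    ----------
    parent_pvalues : the f omnibus p-values (one per filter family).
    children : sequence of f per-family child p-value vectors; NaN entries
        (flagged fits) are excluded from their family's size.
    q : nominal BH level applied within each level of the hierarchy.
    """
    parent_pvalues = np.asarray(parent_pvalues, dtype=float)
    if parent_pvalues.size == 0:
        raise ValueError("parent p-value vector is empty")
    if len(children) != parent_pvalues.size:
        raise ValueError("need exactly one child family per parent")
    parent_q = bh_adjust(parent_pvalues)
    rejected = np.nan_to_num(parent_q, nan=np.inf) <= q
    child_q: list[np.ndarray | None] = []
    child_rej: list[np.ndarray | None] = []
    d = 0
    for i, fam in enumerate(children):
        if not rejected[i]:
            child_q.append(None)
            child_rej.append(None)
            continue
        adj = bh_adjust(np.asarray(fam, dtype=float))
        rej = np.nan_to_num(adj, nan=np.inf) <= q
        d += int(rej.sum())
        child_q.append(adj)
        child_rej.append(rej)
    eff = effective_fdr_level(q, f=parent_pvalues.size, d=d, delta_star=delta_star)
    return HierarchyResult(
        parent_pvalues=parent_pvalues,
        parent_qvalues=parent_q,
        rejected_parents=rejected,
        child_qvalues=child_q,
        child_rejected=child_rej,
        discoveries=d,
        effective_level=eff,
        q=q,
    )
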