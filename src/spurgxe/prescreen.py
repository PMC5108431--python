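"""Score-statistic prescreening.

Before any penalized model is fit, the marker set is reduced to the top
``k`` markers ranked by the absolute centered cross-product between a
target variable and each genotype column:

    a_j = | sum_i (y_i - ybar) * G_ij |

For the marginal-association filter the target is the outcome D; for the
gene-environment-correlation filter it is the exposure E.  This is the
score statistic of the single-marker regression at beta=0, so the ranking
matches single-marker association strength while costing one matrix
product.  A practical working size is k >= 20q where q is the number of
markers the downstream penalized screen will select; no KKT verification
or iterative enlargement of k is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, ParameterError

__all__ = ["PrescreenResult", "score_statistic", "prescreen"]


@dataclass
class PrescreenResult:
    """Scores and the ordered indices of the k retained markers."""

    scores: np.ndarray
    kept_indices: np.ndarray
    k: int
    target_kind: str  # "outcome" or "exposure"


def score_statistic(target: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """Absolute centered cross-product of the target with each column.

    A constant target yields all-zero scores (with a warning): the centered
    vector vanishes identically.
    """
    y = np.asarray(target, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if y.shape[0] != g.shape[0]:
        raise ParameterError(
            f"target length {y.shape[0]} does not match {g.shape[0]} genotype rows"
        )
    centered = y - y.mean()
    if np.all(centered == 0.0):
        warnings.warn("constant target: all prescreen scores are zero", stacklevel=2)
        return np.zeros(g.shape[1])
    return np.abs(centered @ g)


def prescreen(cohort: Cohort, filter: str, k: int) -> PrescreenResult:
    """Rank markers by score statistic and keep the top k.

    ``filter`` is "marginal" (score against the outcome) or "correlation"
    (score against the exposure).  Ties at the retention boundary are broken
    toward the lower marker index for determinism.
    """
    if filter not in ("marginal", "correlation"):
        raise ParameterError(f"unknown filter {filter!r}")
    if not 1 <= k <= cohort.n_markers:
        raise ParameterError(
            f"k={k} must be in [1, p={cohort.n_markers}]"
        )
    target_kind = "outcome" if filter == "marginal" else "exposure"
    target = cohort.outcome if filter == "marginal" else cohort.exposure
    scores = score_statistic(target, cohort.genotypes)
    # stable sort on -scores keeps lower indices first among ties
    order = np.argsort(-scores, kind="stable")
    return PrescreenResult(
        scores=scores,
        kept_indices=order[:k].copy(),
        k=k,
        target_kind=target_kind,
    )
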