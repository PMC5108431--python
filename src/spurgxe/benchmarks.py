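"""Comparison methods: one-step per-SNP testing and classic screening-testing.

The one-step method fits a separate logistic interaction model per marker
and corrects over all p hypotheses.  Classic screening-testing first ranks
markers with a single-marker filter model (marginal association with the
outcome, or association with the exposure), retains the top N, tests each
retained marker with the same per-marker interaction model, and corrects
only over the retained family.  Both serve as baselines for the joint
penalized screening-testing pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, ParameterError
from .fdr import bh_adjust
from .glm import (
    per_snp_interaction_tests,
    per_snp_linear_tests,
    per_snp_marginal_tests,
)

__all__ = ["BenchmarkResult", "one_step", "standard_screening_testing"]


@dataclass
class BenchmarkResult:
    method: str
    tested_indices: np.ndarray
    pvalues: np.ndarray        # per tested marker, NaN for failed fits
    qvalues: np.ndarray        # BH-adjusted within the tested family
    estimates: np.ndarray
    filter_pvalues: np.ndarray | None = None  # screening-stage p per marker

    def significant(self, fdr_q: float) -> np.ndarray:
        """Global indices of markers significant at the given FDR level."""
        ok = np.nan_to_num(self.qvalues, nan=np.inf) <= fdr_q
        return self.tested_indices[ok]


def one_step(cohort: Cohort) -> BenchmarkResult:
    """Per-SNP interaction Wald tests with BH correction over all p markers."""
    C = cohort.covariates if cohort.n_covariates else None
    beta, _se, pval = per_snp_interaction_tests(
        cohort.outcome.astype(float), cohort.genotypes, cohort.exposure, C
    )
    return BenchmarkResult(
        method="one_step",
        tested_indices=np.arange(cohort.n_markers),
        pvalues=pval,
        qvalues=bh_adjust(pval),
        estimates=beta,
    )


def standard_screening_testing(
    cohort: Cohort, filter: str, retain: int
) -> BenchmarkResult:
    """Single-marker filter, top-``retain`` retention, per-marker testing.

    The retained family is the ``retain`` markers with the smallest filter
    p-values (ties toward the lower index); BH runs over that family only.
    """
    if filter not in ("marginal", "correlation"):
        raise ParameterError(f"unknown filter {filter!r}")
    if not 1 <= retain <= cohort.n_markers:
        raise ParameterError(f"retain={retain} must be in [1, p={cohort.n_markers}]")
    C = cohort.covariates if cohort.n_covariates else None
    if filter == "marginal":
        filt_p = per_snp_marginal_tests(
            cohort.outcome.astype(float), cohort.genotypes, C
        )
    elif cohort.exposure_kind == "binary":
        filt_p = per_snp_marginal_tests(cohort.exposure, cohort.genotypes, C)
    else:
        filt_p = per_snp_linear_tests(cohort.exposure, cohort.genotypes, C)
    order = np.argsort(np.nan_to_num(filt_p, nan=np.inf), kind="stable")
    tested = np.sort(order[:retain])
    beta, _se, pval = per_snp_interaction_tests(
        cohort.outcome.astype(float),
        cohort.genotypes[:, tested],
        cohort.exposure,
        C,
    )
    return BenchmarkResult(
        method=f"st_{filter}",
        tested_indices=tested,
        pvalues=pval,
        qvalues=bh_adjust(pval),
        estimates=beta,
        filter_pvalues=filt_p,
    )
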