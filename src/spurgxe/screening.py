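"""Penalized screening stage: select exactly q markers with one model.

The marginal-association filter fits a penalized logistic regression of the
outcome on all prescreened genotype columns; the gene-environment
correlation filter regresses the exposure on the genotypes instead
(penalized logistic for a binary exposure, penalized least squares for a
continuous one).  Covariates, when present, enter unpenalized.  The penalty
is tuned so the number of nonzero genotype coefficients equals the target
q, which fixes the size of the downstream joint test-stage model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, ParameterError
from .enet import EnetSolver
from .prescreen import PrescreenResult

__all__ = ["FilterSpec", "ScreenResult", "fit_screening_model", "default_q"]


@dataclass
class FilterSpec:
    """Which filter to screen with and how many markers to keep."""

    filter: str = "marginal"  # or "correlation"
    alpha: float = 0.999
    q: int = 25
    exposure_kind: str = "binary"

    def __post_init__(self) -> None:
        if self.filter not in ("marginal", "correlation"):
            raise ParameterError(f"unknown filter {self.filter!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must be in [0, 1]")
        if self.q < 1:
            raise ParameterError("q must be >= 1")


@dataclass
class ScreenResult:
    """Markers selected by the penalized screen, in global marker numbering."""

    selected_indices: np.ndarray
    lam: float
    coefficients: np.ndarray  # penalized genotype coefficients for kept markers
    kept_indices: np.ndarray  # prescreen survivors the model was fit on
    filter: str
    achieved_count: int
    truncated: bool


def fit_screening_model(
    cohort: Cohort, kept: PrescreenResult, spec: FilterSpec
) -> ScreenResult:
    """Fit the single elastic-net screening model on the prescreen survivors
    and return the q selected markers (global indices)."""
    kept_idx = np.asarray(kept.kept_indices)
    if spec.q > kept_idx.size:
        raise ParameterError(
            f"q={spec.q} exceeds the {kept_idx.size} prescreened markers"
        )
    G = cohort.genotypes[:, kept_idx].astype(float)
    n_geno = G.shape[1]
    if spec.filter == "marginal":
        y = cohort.outcome.astype(float)
        family = "binomial"
    else:
        y = cohort.exposure.astype(float)
        family = "binomial" if spec.exposure_kind == "binary" else "gaussian"
    if cohort.n_covariates:
        X = np.column_stack([G, cohort.covariates])
        pf = np.concatenate([np.ones(n_geno), np.zeros(cohort.n_covariates)])
    else:
        X = G
        pf = np.ones(n_geno)
    solver = EnetSolver(X, y, alpha=spec.alpha, family=family, penalty_factor=pf)
    fit, choice, _path = solver.fit_for_count(spec.q)
    if choice.truncate:
        local = solver.truncate_to_q(fit, spec.q)
    else:
        local = fit.nonzero_penalized(solver.pf)
    achieved = min(choice.count, spec.q) if choice.count >= spec.q else choice.count
    if achieved < spec.q:
        warnings.warn(
            f"screening achieved only {achieved} nonzero coefficients "
            f"(requested q={spec.q})",
            stacklevel=2,
        )
    return ScreenResult(
        selected_indices=np.sort(kept_idx[local]),
        lam=fit.lam,
        coefficients=fit.coef[:n_geno],
        kept_indices=kept_idx,
        filter=spec.filter,
        achieved_count=len(local),
        truncated=choice.truncate,
    )


def default_q(n: int, n_covariates: int, obs_per_predictor: float = 7.0) -> int:
    """Largest q keeping the test-stage observation-to-predictor ratio.

    The joint test-stage model contains (besides the intercept) the exposure,
    the covariates, q marginal genotype terms and q interaction terms, so the
    rule ``predictors <= n / obs_per_predictor`` gives

        q = floor( (n / ratio - 1 - n_covariates) / 2 ).

    The 7:1 default follows the usual guideline for multiple logistic
    regression.
    """
    if obs_per_predictor <= 0:
        raise ParameterError("obs_per_predictor must be positive")
    if n < obs_per_predictor * (2 + n_covariates + 2):
        raise ParameterError(
            f"n={n} too small to test any marker at a "
            f"{obs_per_predictor}:1 observation-to-predictor ratio"
        )
    return int((n / obs_per_predictor - 1 - n_covariates) // 2)
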