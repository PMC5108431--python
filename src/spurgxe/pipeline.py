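"""Orchestration of the full screening-testing workflow.

Four variants are supported, all sharing the same per-filter branch
(score-statistic prescreen -> elastic-net screen to q markers -> joint
test-stage model):

- ``single_marginal`` / ``single_correlation``: one filter, no omnibus
  gate; the q interaction Wald p-values are BH-adjusted directly.
- ``hierarchical``: both filters run in parallel; the two omnibus LR
  p-values form the parent family of a two-level hierarchical FDR, and the
  per-interaction Wald tests form the child families under rejected
  parents.  The effective level bound q(d+f)/(d+1) is reported.
- ``global``: both filters run; BH is applied to the two omnibus p-values
  only, and every interaction term in a test-stage model inherits its
  model's omnibus q-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ParameterError
from .fdr import bh_adjust, hierarchical_fdr, HierarchyResult
from .prescreen import prescreen
from .screening import FilterSpec, ScreenResult, fit_screening_model
from .teststage import TestStageFit, fit_test_stage

__all__ = ["SpurConfig", "SpurResult", "run_spur", "spur_branch"]

MODES = ("single_marginal", "single_correlation", "hierarchical", "global")


@dataclass
class SpurConfig:
    """Configuration of one pipeline run.

    ``k`` is the prescreen retention count (a comfortable working size is
    k >= 20q; smaller values draw a warning, not an error) and ``q`` the
    number of markers the penalized screen selects for the test stage.
    """

    mode: str = "hierarchical"
    k: int = 100
    q: int = 5
    alpha: float = 0.999
    fdr_q: float = 0.1
    n_retain_global: int | None = None  # default: q

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.k < self.q:
            raise ParameterError(f"k={self.k} must be >= q={self.q}")
        if self.k < 20 * self.q:
            warnings.warn(
                f"prescreen k={self.k} is below the recommended 20*q={20 * self.q}",
                stacklevel=2,
            )


@dataclass
class SpurResult:
    mode: str
    screens: dict[str, ScreenResult]
    fits: dict[str, TestStageFit]
    omnibus: pd.DataFrame                 # filter, lr_stat, df, pvalue, qvalue
    interactions: pd.DataFrame            # marker, filter, estimate, p, FDR, significant
    hierarchy: HierarchyResult | None = None
    effective_level: float | None = None
    config: SpurConfig | None = None

    def significant(self) -> pd.DataFrame:
        return self.interactions[self.interactions["significant"]]


def spur_branch(
    cohort: Cohort, filt: str, k: int, q: int, alpha: float = 0.999
) -> tuple[ScreenResult, TestStageFit]:
    """One filter branch: prescreen -> penalized screen -> joint test stage."""
    pres = prescreen(cohort, filt, k)
    spec = FilterSpec(
        filter=filt, alpha=alpha, q=q, exposure_kind=cohort.exposure_kind
    )
    screen = fit_screening_model(cohort, pres, spec)
    fit = fit_test_stage(cohort, screen.selected_indices)
    return screen, fit


def _interaction_frame(
    cohort: Cohort, filt: str, fit: TestStageFit, fdr: np.ndarray, sig: np.ndarray
) -> pd.DataFrame:
    tab = fit.wald.copy()
    tab.insert(1, "filter", filt)
    tab["fdr"] = fdr
    tab["significant"] = sig
    return tab


def run_spur(cohort: Cohort, config: SpurConfig) -> SpurResult:
    """Run the configured workflow variant on a cohort."""
    if config.mode == "single_marginal":
        filters = ["marginal"]
    elif config.mode == "single_correlation":
        filters = ["correlation"]
    else:
        filters = ["marginal", "correlation"]

    q_screen = config.q
    if config.mode == "global" and config.n_retain_global is not None:
        q_screen = config.n_retain_global

    screens: dict[str, ScreenResult] = {}
    fits: dict[str, TestStageFit] = {}
    for filt in filters:
        screens[filt], fits[filt] = spur_branch(
            cohort, filt, config.k, q_screen, config.alpha
        )

    omni = pd.DataFrame(
        {
            "filter": filters,
            "lr_stat": [fits[f].lr_stat for f in filters],
            "df": [fits[f].lr_df for f in filters],
            "pvalue": [fits[f].lr_pvalue for f in filters],
        }
    )
    omni["qvalue"] = bh_adjust(omni["pvalue"].to_numpy())

    frames = []
    hierarchy = None
    effective = None
    if config.mode in ("single_marginal", "single_correlation"):
        filt = filters[0]
        p = fits[filt].wald["pvalue"].to_numpy()
        fdr = bh_adjust(p)
        sig = np.nan_to_num(fdr, nan=np.inf) <= config.fdr_q
        frames.append(_interaction_frame(cohort, filt, fits[filt], fdr, sig))
    elif config.mode == "hierarchical":
        children = [fits[f].wald["pvalue"].to_numpy() for f in filters]
        hierarchy = hierarchical_fdr(
            omni["pvalue"].to_numpy(), children, q=config.fdr_q
        )
        effective = hierarchy.effective_level
        for i, filt in enumerate(filters):
            if hierarchy.child_qvalues[i] is None:
                fdr = np.full(len(children[i]), np.nan)
                sig = np.zeros(len(children[i]), dtype=bool)
            else:
                fdr = hierarchy.child_qvalues[i]
                sig = hierarchy.child_rejected[i]
            frames.append(_interaction_frame(cohort, filt, fits[filt], fdr, sig))
    else:  # global
        for i, filt in enumerate(filters):
            model_q = omni["qvalue"].iloc[i]
            nterms = len(fits[filt].wald)
            fdr = np.full(nterms, model_q)
            sig = np.full(nterms, model_q <= config.fdr_q)
            frames.append(_interaction_frame(cohort, filt, fits[filt], fdr, sig))

    interactions = pd.concat(frames, ignore_index=True)
    return SpurResult(
        mode=config.mode,
        screens=screens,
        fits=fits,
        omnibus=omni,
        interactions=interactions,
        hierarchy=hierarchy,
        effective_level=effective,
        config=config,
    )
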