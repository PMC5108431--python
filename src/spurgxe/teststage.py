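"""Joint unpenalized test-stage model with omnibus and per-interaction tests.

A single multiple logistic regression contains the exposure, covariates,
and a marginal plus an interaction term for each of the q screened markers:

    logit P(D=1) = b0 + bE*E + covariates + sum_i bGi*Gi + sum_i bGiE*Gi*E

The omnibus likelihood-ratio test compares this model against the nested
model without any interaction terms (null: all interaction coefficients
zero; chi-square with q degrees of freedom).  Individual interactions are
tested with two-sided Wald tests by default; per-term LR tests are
available behind a flag.  Quasi-separated coefficients (|estimate| beyond
15 on the logit scale) are flagged and their p-values reported missing so
they cannot contaminate downstream FDR families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .cohort import Cohort, ParameterError

SEPARATION_BOUND = 15.0

__all__ = ["TestStageFit", "fit_test_stage", "wald_tests"]


@dataclass
class TestStageFit:
    selected_indices: np.ndarray
    marker_ids: list[str]
    params: pd.Series
    bse: pd.Series
    loglik_full: float
    loglik_reduced: float
    lr_stat: float
    lr_df: int
    lr_pvalue: float
    wald: pd.DataFrame
    converged: bool = True
    dropped_terms: list[str] = field(default_factory=list)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                res = model.fit(disp=0, method="bfgs", maxiter=1000)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=1000)
    return res


def _drop_aliased(X: np.ndarray, names: list[str]):
    """Greedily drop columns that do not increase the design rank."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank == k:
        return X, names, []
    keep: list[int] = []
    dropped: list[str] = []
    current = np.empty((n, 0))
    for j in range(k):
        cand = np.column_stack([current, X[:, j]])
        if np.linalg.matrix_rank(cand) > current.shape[1]:
            keep.append(j)
            current = cand
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def fit_test_stage(
    cohort: Cohort,
    selected: np.ndarray,
    per_term_lr: bool = False,
) -> TestStageFit:
    """Fit the joint test-stage model for the given (global) marker indices."""
    selected = np.asarray(selected, dtype=int)
    if selected.size < 1:
        raise ParameterError("test stage needs at least one selected marker")
    y = cohort.outcome.astype(float)
    n = cohort.n_subjects
    G = cohort.genotypes[:, selected].astype(float)
    E = cohort.exposure
    ids = [cohort.marker_ids[j] for j in selected]
    base_cols = [np.ones(n), E] + [
        cohort.covariates[:, i] for i in range(cohort.n_covariates)
    ]
    base_names = ["intercept", "exposure"] + [
        f"cov{i + 1}" for i in range(cohort.n_covariates)
    ]
    marg_names = [f"G:{m}" for m in ids]
    int_names = [f"GxE:{m}" for m in ids]
    X_full = np.column_stack(base_cols + [G, G * E[:, None]])
    names_full = base_names + marg_names + int_names
    X_full, names_full, dropped = _drop_aliased(X_full, names_full)
    res_full = _fit_logit(y, X_full)

    kept_int = [nm for nm in names_full if nm.startswith("GxE:")]
    X_red = X_full[:, [i for i, nm in enumerate(names_full) if not nm.startswith("GxE:")]]
    res_red = _fit_logit(y, X_red)

    lr_df = len(kept_int)
    lr_stat = max(0.0, 2.0 * (res_full.llf - res_red.llf))
    lr_pvalue = float(chi2.sf(lr_stat, lr_df)) if lr_df > 0 else 1.0

    params = pd.Series(res_full.params, index=names_full)
    bse = pd.Series(res_full.bse, index=names_full)
    converged = bool(res_full.mle_retvals.get("converged", True))

    rows = []
    for j, marker in zip(selected, ids):
        nm = f"GxE:{marker}"
        if nm not in params.index:
            rows.append((marker, j, np.nan, np.nan, np.nan, np.nan, "aliased"))
            continue
        est, se = params[nm], bse[nm]
        flag = ""
        if abs(est) > SEPARATION_BOUND:
            flag = "separated"
        elif not converged:
            flag = "nonconverged"
        elif not np.isfinite(se) or se <= 0:
            flag = "se_undefined"
        if flag:
            z = p = np.nan
        elif per_term_lr:
            cols = [i for i, name in enumerate(names_full) if name != nm]
            res_drop = _fit_logit(y, X_full[:, cols])
            stat = max(0.0, 2.0 * (res_full.llf - res_drop.llf))
            p = float(chi2.sf(stat, 1))
            z = np.sign(est) * np.sqrt(stat)
        else:
            z = est / se
            p = float(2.0 * norm.sf(abs(z)))
        rows.append((marker, j, est, se, z, p, flag))
    wald = pd.DataFrame(
        rows, columns=["marker_id", "index", "estimate", "se", "z", "pvalue", "flag"]
    )
    if not converged or np.abs(params.values).max() > SEPARATION_BOUND:
        lr_flagged = not converged
        if lr_flagged:
            lr_pvalue = float(lr_pvalue)  # reported but converged=False marks it
    return TestStageFit(
        selected_indices=selected,
        marker_ids=ids,
        params=params,
        bse=bse,
        loglik_full=float(res_full.llf),
        loglik_reduced=float(res_red.llf),
        lr_stat=float(lr_stat),
        lr_df=lr_df,
        lr_pvalue=lr_pvalue,
        wald=wald,
        converged=converged,
        dropped_terms=dropped,
    )


def wald_tests(fit: TestStageFit) -> pd.DataFrame:
    """Per-interaction test table (one row per selected marker)."""
    return fit.wald.copy()
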