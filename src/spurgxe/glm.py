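"""Vectorized per-marker regression fits.

The one-step method and the single-marker filters need thousands of tiny
logistic regressions per simulated data set (one 2-4 parameter model per
SNP), so models are fitted in batches with a Newton-Raphson iteration
vectorized across markers.  Coefficients whose magnitude diverges past
``SEPARATION_BOUND`` on the logit scale are flagged as (quasi-)separated
and their p-values reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

SEPARATION_BOUND = 15.0


@dataclass
class BatchGlmResult:
    params: np.ndarray      # (m, k)
    bse: np.ndarray         # (m, k)
    converged: np.ndarray   # (m,) bool
    separated: np.ndarray   # (m,) bool

    def wald_pvalues(self, coef_index: int) -> np.ndarray:
        """Two-sided normal p-values for one coefficient across the batch.

        Non-converged or separated fits get NaN.
        """
        z = self.params[:, coef_index] / self.bse[:, coef_index]
        p = 2.0 * norm.sf(np.abs(z))
        p[~self.converged | self.separated] = np.nan
        return p


def fit_logistic_batch(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
    ridge: float = 1e-9,
) -> BatchGlmResult:
    """Fit m logistic regressions y ~ X[i] for a stacked design (m, n, k)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n, k = X.shape
    B = np.zeros((m, k))
    eye = ridge * np.eye(k)
    Xt = X.transpose(0, 2, 1)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    H = np.empty((m, k, k))
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa = X[idx]
        eta = np.clip(np.einsum("mnk,mk->mn", Xa, B[idx]), -30.0, 30.0)
        p = expit(eta)
        w = p * (1.0 - p) + 1e-12
        g = np.einsum("mkn,mn->mk", Xt[idx], y[None, :] - p)
        Ha = np.einsum("mkn,mnl->mkl", Xt[idx] * w[:, None, :], Xa) + eye
        H[idx] = Ha
        try:
            delta = np.linalg.solve(Ha, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(Ha + 1e-6 * np.eye(k), g[..., None])[..., 0]
        B[idx] += delta
        done = np.abs(delta).max(axis=1) < tol
        # freeze clearly diverging fits; they are flagged below
        diverged = np.abs(B[idx]).max(axis=1) > 4 * SEPARATION_BOUND
        converged[idx[done]] = True
        active[idx[done | diverged]] = False
    separated = np.abs(B).max(axis=1) > SEPARATION_BOUND
    cov = np.linalg.inv(H)
    bse = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return BatchGlmResult(params=B, bse=bse, converged=converged, separated=separated)


def _stack_designs(columns: list[np.ndarray | None], G_blocks: dict[int, np.ndarray]) -> np.ndarray:
    """Build an (m, n, k) stacked design from shared columns (n,) and
    per-marker columns (n, m) keyed by slot index."""
    m = next(iter(G_blocks.values())).shape[1]
    n = columns[0].shape[0] if columns[0] is not None else next(iter(G_blocks.values())).shape[0]
    k = len(columns)
    X = np.empty((m, n, k))
    for slot, col in enumerate(columns):
        if slot in G_blocks:
            X[:, :, slot] = G_blocks[slot].T
        else:
            X[:, :, slot] = col[None, :]
    return X


def _chunks(p: int, size: int):
    for start in range(0, p, size):
        yield np.arange(start, min(start + size, p))


def per_snp_interaction_tests(
    y: np.ndarray,
    G: np.ndarray,
    E: np.ndarray,
    C: np.ndarray | None = None,
    chunk: int = 128,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic model D ~ 1 + G_j + E + G_j*E (+ covariates).

    Returns (betaGE, se, pvalue) arrays of length p; the interaction
    coefficient is tested with a two-sided Wald test.  Failed fits give NaN.
    """
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    ones = np.ones(n)
    cov_cols = [C[:, i] for i in range(C.shape[1])] if C is not None else []
    beta = np.empty(p)
    se = np.empty(p)
    pval = np.empty(p)
    for cols in _chunks(p, chunk):
        Gc = G[:, cols]
        blocks = {1: Gc, 3: Gc * E[:, None]}
        design_cols = [ones, None, E, None] + cov_cols
        X = _stack_designs(design_cols, blocks)
        res = fit_logistic_batch(y, X)
        beta[cols] = res.params[:, 3]
        se[cols] = res.bse[:, 3]
        pval[cols] = res.wald_pvalues(3)
    return beta, se, pval


def per_snp_marginal_tests(
    y: np.ndarray, G: np.ndarray, C: np.ndarray | None = None, chunk: int = 256
) -> np.ndarray:
    """Wald p-values for betaG in the per-SNP logistic model y ~ 1 + G_j (+C)."""
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    ones = np.ones(n)
    cov_cols = [C[:, i] for i in range(C.shape[1])] if C is not None else []
    pval = np.empty(p)
    for cols in _chunks(p, chunk):
        X = _stack_designs([ones, None] + cov_cols, {1: G[:, cols]})
        res = fit_logistic_batch(y, X)
        pval[cols] = res.wald_pvalues(1)
    return pval


def per_snp_linear_tests(
    y: np.ndarray, G: np.ndarray, C: np.ndarray | None = None
) -> np.ndarray:
    """t-test p-values for the slope in per-SNP linear models y ~ 1 + G_j (+C).

    Used for the gene-environment-correlation filter with a continuous
    exposure.  Covariates are projected out of both sides first
    (Frisch-Waugh-Lovell), leaving a vectorized simple-regression t-test.
    """
    from scipy.stats import t as t_dist

    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = G.shape
    Z = np.ones((n, 1)) if C is None or C.shape[1] == 0 else np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(Z)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    gss = (Gr * Gr).sum(axis=0)
    gss_safe = np.where(gss > 0, gss, np.nan)
    slope = (Gr.T @ yr) / gss_safe
    df = n - Z.shape[1] - 1
    resid_ss = (yr @ yr) - slope**2 * gss_safe
    sigma2 = resid_ss / df
    se = np.sqrt(sigma2 / gss_safe)
    tstat = slope / se
    return 2.0 * t_dist.sf(np.abs(tstat), df)
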