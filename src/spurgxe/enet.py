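"""Elastic-net penalized regression with count-targeted penalty selection.

The screening stage fits a single penalized multiple regression of the
outcome (marginal-association filter) or the exposure (gene-environment
correlation filter) on all retained genotype columns, minimizing

    -loglik(beta)/n + lambda * [ (1-alpha)/2 * sum beta_j^2 + alpha * sum |beta_j| ]

over standardized predictors, with the intercept and any covariates left
unpenalized.  ``alpha`` close to 1 (default 0.999 upstream) is lasso-like
with a whisper of ridge for stability.  The solver is a proximal-Newton /
coordinate-descent scheme in the glmnet mold: an outer IRLS loop builds a
weighted least-squares approximation, and an inner cyclic coordinate
descent with active-set iterations solves it.  For the problem sizes the
pipeline produces (n of order 1000, tens to a few hundred predictors after
prescreening) the inner loop works on the weighted Gram matrix, which makes
a full sweep O(p^2) instead of O(n p).

Because the goal of screening is "select exactly q markers", the penalty is
chosen by descending a geometric lambda path from lambda_max (the smallest
penalty with all coefficients zero) until at least q coefficients are
active, then bisecting the bracketing interval.  Coordinate-descent paths
can skip counts when correlated predictors enter together; if the bracket
collapses without hitting q exactly, the fit with the smallest count >= q
is truncated to the q largest standardized coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "EnetSolver",
    "EnetFit",
    "DegenerateScreenError",
    "select_lambda_for_q",
    "LambdaChoice",
]


class DegenerateScreenError(RuntimeError):
    """No penalty on the path yields any nonzero penalized coefficient."""


@dataclass
class EnetFit:
    """A fitted penalized model on the original predictor scale."""

    intercept: float
    coef: np.ndarray
    lam: float
    alpha: float
    converged: bool
    # standardized-scale state, used for warm starts and truncation
    beta_std: np.ndarray | None = None
    intercept_std: float = 0.0

    def nonzero_penalized(self, penalty_factor: np.ndarray) -> np.ndarray:
        return np.flatnonzero((penalty_factor > 0) & (self.beta_std != 0.0))


@dataclass
class LambdaChoice:
    """Result of count-targeted penalty selection."""

    lam: float
    count: int
    truncate: bool


def select_lambda_for_q(path, q: int, refit=None, max_bisect: int = 45) -> LambdaChoice:
    """Pick the penalty whose nonzero count equals q from a (lam, count) path.

    ``path`` must be sorted by decreasing lambda.  If q falls strictly
    between two path points and a ``refit`` callable (lambda -> count) is
    supplied, the bracket is bisected on the log scale until the count hits
    q or the bracket collapses; on collapse the smaller lambda is returned
    with ``truncate=True`` so the caller keeps the q largest coefficients.
    If q exceeds every count on the path, the lambda of the largest count is
    returned with a warning.
    """
    path = list(path)
    if not path:
        raise ValueError("empty lambda path")
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    hi_lam = None  # largest-lambda side, count < q
    for lam, count in path:
        if count == q:
            return LambdaChoice(lam=lam, count=count, truncate=False)
        if count > q:
            if hi_lam is None or refit is None:
                return LambdaChoice(lam=lam, count=count, truncate=True)
            lo_lam, lo_count = lam, count
            best = (lo_lam, lo_count)
            for _ in range(max_bisect):
                if hi_lam / lo_lam < 1.0 + 1e-6:
                    break
                mid = math.sqrt(hi_lam * lo_lam)
                c = refit(mid)
                if c == q:
                    return LambdaChoice(lam=mid, count=c, truncate=False)
                if c < q:
                    hi_lam = mid
                else:
                    lo_lam = mid
                    if c < best[1]:
                        best = (mid, c)
            return LambdaChoice(lam=best[0], count=best[1], truncate=True)
        hi_lam = lam
    best_lam, best_count = max(path, key=lambda t: (t[1], t[0]))
    warnings.warn(
        f"requested q={q} not achievable on the path; best count is {best_count}",
        stacklevel=2,
    )
    return LambdaChoice(lam=best_lam, count=best_count, truncate=False)


class EnetSolver:
    """Warm-startable elastic-net solver bound to one (X, y) problem.

    Parameters
    ----------
    X : (n, p) predictor matrix (genotypes, plus any covariate columns).
    y : response; {0,1} for family="binomial", real for family="gaussian".
    alpha : elastic-net mixing parameter in [0, 1].
    family : "binomial" or "gaussian".
    penalty_factor : per-column multipliers on the penalty; 0 leaves a
        column (e.g. a covariate) unpenalized.  Default all ones.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        alpha: float = 0.999,
        family: str = "binomial",
        penalty_factor: np.ndarray | None = None,
        tol: float = 1e-7,
        max_outer: int = 100,
        max_sweeps: int = 100000,
    ) -> None:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        if family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {family!r}")
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        self.y = np.asarray(y, dtype=float)
        self.alpha = alpha
        self.family = family
        self.tol = tol
        self.max_outer = max_outer
        self.max_sweeps = max_sweeps
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.degenerate_cols = sd == 0.0
        sd = np.where(self.degenerate_cols, 1.0, sd)
        self.sd = sd
        self.Xs = (X - self.mu) / sd
        self.pf = (
            np.ones(self.p)
            if penalty_factor is None
            else np.asarray(penalty_factor, dtype=float)
        )

    # -- core WLS coordinate descent on the Gram matrix -----------------------
    def _cd_wls(self, w, z, beta, b0, l1, l2):
        """Minimize (1/2n) sum w_i (z_i - b0 - Xs beta)^2 + penalty."""
        Xs, n, p = self.Xs, self.n, self.p
        A = (Xs.T * w) @ Xs / n                   # weighted Gram
        bvec = (Xs.T @ (w * z)) / n
        cvec = (Xs.T @ w) / n
        sw = w.sum() / n
        mz = (w @ z) / n
        diag = np.diag(A).copy()
        u = A @ beta
        tol = self.tol
        all_idx = np.arange(p)

        def sweep(indices):
            nonlocal b0, u
            max_delta = 0.0
            for j in indices:
                dj = diag[j]
                if dj <= 1e-12:
                    continue
                bj = beta[j]
                num = bvec[j] - b0 * cvec[j] - u[j] + dj * bj
                t = l1[j]
                if t > 0.0:
                    bn = math.copysign(max(abs(num) - t, 0.0), num) / (dj + l2[j])
                else:
                    bn = num / (dj + l2[j])
                if bn != bj:
                    beta[j] = bn
                    u += A[:, j] * (bn - bj)
                    step = dj * (bn - bj) ** 2
                    if step > max_delta:
                        max_delta = step
            # intercept (always unpenalized)
            b0_new = (mz - float(cvec @ beta)) / sw
            if b0_new != b0:
                step = sw * (b0_new - b0) ** 2
                if step > max_delta:
                    max_delta = step
                b0 = b0_new
            return max_delta

        sweeps = 0
        converged = False
        while sweeps < self.max_sweeps:
            md = sweep(all_idx)
            sweeps += 1
            if md < tol:
                converged = True
                break
            active = np.flatnonzero(beta)
            while sweeps < self.max_sweeps:
                md = sweep(active)
                sweeps += 1
                if md < tol:
                    break
        return beta, b0, converged

    def _penalized_objective(self, beta, b0, lam):
        eta = b0 + self.Xs @ beta
        if self.family == "binomial":
            # numerically stable -loglik/n
            nll = np.mean(np.logaddexp(0.0, eta) - self.y * eta)
        else:
            nll = 0.5 * np.mean((self.y - eta) ** 2)
        pen = lam * (
            (1.0 - self.alpha) / 2.0 * float(self.pf @ (beta**2))
            + self.alpha * float(self.pf @ np.abs(beta))
        )
        return nll + pen

    def fit(self, lam: float, warm: EnetFit | None = None) -> EnetFit:
        """Fit at a single penalty value, optionally warm-started."""
        l1 = lam * self.alpha * self.pf
        l2 = lam * (1.0 - self.alpha) * self.pf
        if warm is not None and warm.beta_std is not None:
            beta = warm.beta_std.copy()
            b0 = warm.intercept_std
        else:
            beta = np.zeros(self.p)
            if self.family == "binomial":
                ybar = min(max(self.y.mean(), 1e-10), 1.0 - 1e-10)
                b0 = math.log(ybar / (1.0 - ybar))
            else:
                b0 = float(self.y.mean())
        if self.family == "gaussian":
            w = np.ones(self.n)
            beta, b0, conv = self._cd_wls(w, self.y, beta, b0, l1, l2)
        else:
            conv = False
            obj = self._penalized_objective(beta, b0, lam)
            for _ in range(self.max_outer):
                eta = np.clip(b0 + self.Xs @ beta, -30.0, 30.0)
                pr = expit(eta)
                w = np.clip(pr * (1.0 - pr), 1e-5, None)
                z = eta + (self.y - pr) / w
                beta, b0, _ = self._cd_wls(w, z, beta, b0, l1, l2)
                obj_new = self._penalized_objective(beta, b0, lam)
                if abs(obj - obj_new) < self.tol * (abs(obj) + 1e-10):
                    conv = True
                    break
                obj = obj_new
        coef = beta / self.sd
        intercept = b0 - float(coef @ self.mu)
        return EnetFit(
            intercept=intercept,
            coef=coef,
            lam=lam,
            alpha=self.alpha,
            converged=conv,
            beta_std=beta,
            intercept_std=b0,
        )

    def lambda_max(self) -> float:
        """Smallest penalty at which every penalized coefficient is zero.

        Derived from the KKT conditions at the null (intercept + unpenalized
        columns only) model: lambda_max = max_j |x_j' r0| / (n * alpha * pf_j).
        """
        if np.any(self.pf == 0.0):
            null_fit = self.fit(lam=1e9)
            eta = null_fit.intercept_std + self.Xs @ null_fit.beta_std
            r0 = (
                self.y - expit(eta)
                if self.family == "binomial"
                else self.y - eta
            )
        else:
            r0 = self.y - self.y.mean()
        grads = np.abs(self.Xs.T @ r0) / self.n
        pen = self.pf > 0.0
        alpha = max(self.alpha, 1e-3)
        return float(np.max(grads[pen] / (alpha * self.pf[pen])))

    def count_nonzero(self, fit: EnetFit) -> int:
        return int(np.count_nonzero((self.pf > 0) & (fit.beta_std != 0.0)))

    # -- count-targeted selection ---------------------------------------------
    def fit_for_count(
        self, q: int, path_shrink: float = 0.82, min_lam_ratio: float = 1e-6
    ) -> tuple[EnetFit, LambdaChoice, list[tuple[float, int]]]:
        """Descend the lambda path until exactly q penalized coefficients are
        nonzero (bisecting if the path skips q); see module docstring."""
        n_pen = int(np.count_nonzero(self.pf > 0))
        if q > n_pen:
            raise ValueError(f"q={q} exceeds {n_pen} penalized predictors")
        lam_max = self.lambda_max()
        lam = lam_max * 1.000001
        fit = self.fit(lam)
        path: list[tuple[float, int]] = [(lam, self.count_nonzero(fit))]
        fits = {lam: fit}
        while path[-1][1] < q:
            lam *= path_shrink
            fit = self.fit(lam, warm=fit)
            count = self.count_nonzero(fit)
            path.append((lam, count))
            fits[lam] = fit
            if lam < lam_max * min_lam_ratio:
                break
        if max(c for _, c in path) == 0:
            raise DegenerateScreenError(
                "no penalty on the path yields a nonzero penalized coefficient"
            )

        warm_holder = {"fit": fit}

        def refit(lam_mid: float) -> int:
            f = self.fit(lam_mid, warm=warm_holder["fit"])
            fits[lam_mid] = f
            warm_holder["fit"] = f
            return self.count_nonzero(f)

        choice = select_lambda_for_q(path, q, refit=refit)
        chosen = fits.get(choice.lam)
        if chosen is None or self.count_nonzero(chosen) != choice.count:
            chosen = self.fit(choice.lam, warm=fit)
        return chosen, choice, path

    def truncate_to_q(self, fit: EnetFit, q: int) -> np.ndarray:
        """Indices (into X's columns) of the q largest-|standardized coef|
        nonzero penalized coefficients, ties toward the lower index."""
        nz = fit.nonzero_penalized(self.pf)
        mags = np.abs(fit.beta_std[nz])
        order = np.argsort(-mags, kind="stable")[:q]
        return np.sort(nz[order])
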