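"""Tests of the elastic-net coordinate-descent solver."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from spurgxe import EnetSolver, LambdaChoice, select_lambda_for_q


def _toy_problem(seed=0, n=300, p=12, family="binomial"):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, (n, p)).astype(float)
    beta = np.zeros(p)
    beta[:3] = [0.8, -0.6, 0.5]
    eta = -0.5 + X @ beta
    if family == "binomial":
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    else:
        y = eta + rng.standard_normal(n)
    return X, y


def test_full_shrinkage_above_lambda_max():
    X, y = _toy_problem()
    solver = EnetSolver(X, y, alpha=0.999)
    fit = solver.fit(solver.lambda_max() * 1.01)
    assert solver.count_nonzero(fit) == 0


def test_small_lambda_approaches_unpenalized_mle():
    import statsmodels.api as sm

    X, y = _toy_problem(seed=1, p=5)
    solver = EnetSolver(X, y, alpha=0.999, tol=1e-10)
    fit = solver.fit(1e-8)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert abs(fit.intercept - ref.params[0]) < 1e-3
    np.testing.assert_allclose(fit.coef, ref.params[1:], atol=1e-3)


def test_ridge_keeps_all_coefficients_nonzero():
    X, y = _toy_problem(seed=2)
    solver = EnetSolver(X, y, alpha=0.0)
    fit = solver.fit(0.05)
    assert solver.count_nonzero(fit) == X.shape[1]


def test_gaussian_family_matches_ols_at_zero_penalty():
    X, y = _toy_problem(seed=3, family="gaussian")
    solver = EnetSolver(X, y, alpha=0.999, family="gaussian", tol=1e-12)
    fit = solver.fit(1e-10)
    ref = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)[0]
    np.testing.assert_allclose(fit.coef, ref[1:], atol=1e-5)


def test_selection_invariant_to_column_order():
    X, y = _toy_problem(seed=4, p=20)
    solver = EnetSolver(X, y, alpha=0.999)
    fit, choice, _ = solver.fit_for_count(4)
    sel = solver.truncate_to_q(fit, 4) if choice.truncate else fit.nonzero_penalized(solver.pf)

    perm = np.random.default_rng(5).permutation(20)
    solver2 = EnetSolver(X[:, perm], y, alpha=0.999)
    fit2, choice2, _ = solver2.fit_for_count(4)
    sel2 = solver2.truncate_to_q(fit2, 4) if choice2.truncate else fit2.nonzero_penalized(solver2.pf)
    assert set(perm[sel2]) == set(sel)


def test_unpenalized_covariate_column_survives_heavy_penalty():
    rng = np.random.default_rng(6)
    n = 400
    cov = rng.standard_normal(n)
    X = np.column_stack([rng.integers(0, 3, (n, 6)).astype(float), cov])
    eta = -0.2 + 1.5 * cov
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    pf = np.array([1.0] * 6 + [0.0])
    solver = EnetSolver(X, y, alpha=0.999, penalty_factor=pf)
    fit = solver.fit(solver.lambda_max() * 1.01)
    assert solver.count_nonzero(fit) == 0       # genotypes fully shrunk
    assert abs(fit.coef[-1]) > 0.5              # covariate fitted freely


def test_select_lambda_for_q_path_cases():
    assert select_lambda_for_q([(1.0, 0), (0.5, 3), (0.25, 5)], 5) == LambdaChoice(0.25, 5, False)
    # q skipped on the path, no refitter: smaller lambda + truncation
    c = select_lambda_for_q([(1.0, 0), (0.5, 3), (0.25, 8)], 5)
    assert c.lam == 0.25 and c.truncate
    # q skipped, refit hits it exactly via bisection
    counts = {0.5: 3, 0.25: 8}

    def refit(lam):
        return 5 if 0.3 < lam < 0.45 else (3 if lam >= 0.45 else 8)

    c2 = select_lambda_for_q([(1.0, 0), (0.5, 3), (0.25, 8)], 5, refit=refit)
    assert c2.count == 5 and not c2.truncate and 0.25 < c2.lam < 0.5
    with pytest.raises(ValueError):
        select_lambda_for_q([], 3)
    with pytest.warns(UserWarning, match="not achievable"):
        c3 = select_lambda_for_q([(1.0, 0), (0.5, 2)], 5)
    assert c3.count == 2


def test_exact_count_on_simulated_screen():
    X, y = _toy_problem(seed=7, n=500, p=40)
    solver = EnetSolver(X, y, alpha=0.999)
    fit, choice, path = solver.fit_for_count(10)
    sel = solver.truncate_to_q(fit, 10) if choice.truncate else fit.nonzero_penalized(solver.pf)
    assert len(sel) == 10
    # path is decreasing in lambda
    lams = [l for l, _ in path]
    assert all(a > b for a, b in zip(lams, lams[1:]))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_glmnet_oracle(tmp_path):
    """Independent cross-check of the coordinate descent against R glmnet."""
    X, y = _toy_problem(seed=8, n=250, p=8)
    lam = 0.02
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y, delimiter=",")
    rcode = textwrap.dedent(
        f"""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
        y <- scan("{tmp_path}/y.csv", quiet=TRUE)
        fit <- glmnet(X, y, family="binomial", alpha=0.999,
                      lambda=c(0.2, 0.1, 0.05, {lam}), standardize=TRUE,
                      thresh=1e-12)
        co <- as.numeric(coef(fit, s={lam}))
        cat(co, sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-"], input=rcode, capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    ref = np.array([float(v) for v in out.stdout.split()])
    solver = EnetSolver(X, y, alpha=0.999, tol=1e-12)
    fit = solver.fit(lam)
    assert abs(fit.intercept - ref[0]) < 5e-3
    np.testing.assert_allclose(fit.coef, ref[1:], atol=5e-3)
    # same sparsity pattern
    assert np.array_equal(fit.coef != 0, ref[1:] != 0)
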