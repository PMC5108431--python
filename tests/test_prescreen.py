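"""Tests of the score-statistic prescreen."""

import numpy as np
import pytest

from spurgxe import ParameterError, prescreen, score_statistic
from spurgxe.cohort import Cohort


def brute_force_scores(y, G):
    n, p = G.shape
    ybar = sum(y) / n
    out = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += (y[i] - ybar) * G[i, j]
        out[j] = abs(s)
    return out


def test_hand_computed_score():
    y = np.array([1.0, 0.0])
    G = np.array([[1], [0]])
    assert score_statistic(y, G)[0] == pytest.approx(0.5)


def test_constant_column_scores_zero():
    y = np.array([1.0, 0.0, 1.0, 0.0])
    G = np.column_stack([np.full(4, 2), np.array([0, 1, 2, 0])])
    s = score_statistic(y, G)
    assert s[0] == pytest.approx(0.0, abs=1e-12)


def test_score_linearity_in_column_scale():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 30).astype(float)
    g = rng.integers(0, 3, 30).astype(float)
    s1 = score_statistic(y, g[:, None])[0]
    s2 = score_statistic(y, (2 * g)[:, None])[0]
    assert s2 == pytest.approx(2 * s1)


def test_matches_two_loop_oracle():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50).astype(float)
    G = rng.integers(0, 3, (50, 20)).astype(float)
    np.testing.assert_allclose(
        score_statistic(y, G), brute_force_scores(y, G), rtol=1e-10, atol=1e-10
    )


def test_constant_target_warns_and_zeroes():
    G = np.array([[0, 1], [1, 2], [2, 0]])
    with pytest.warns(UserWarning, match="constant target"):
        s = score_statistic(np.ones(3), G)
    assert np.all(s == 0)


def _cohort_from(G, y, E):
    return Cohort(genotypes=G, exposure=E, outcome=y)


def test_topk_selection_and_ties():
    # y = (1,0,1,0): score_j = 0.5 * |G1j - G2j + G3j - G4j|
    y = np.array([1, 0, 1, 0])
    G = np.array(
        [
            [1, 1, 2],
            [0, 1, 0],
            [0, 0, 0],
            [0, 0, 0],
        ]
    )  # scores (0.5, 0.0, 1.0)
    res = prescreen(_cohort_from(G, y, np.zeros(4)), "marginal", 2)
    assert list(res.kept_indices) == [2, 0]

    # exact ties break toward the lower marker index
    G2 = np.array(
        [
            [1, 0, 1],
            [0, 0, 1],
            [0, 1, 0],
            [0, 0, 0],
        ]
    )  # scores (0.5, 0.5, 0.0)
    res2 = prescreen(_cohort_from(G2, y, np.zeros(4)), "marginal", 1)
    assert list(res2.kept_indices) == [0]


def test_k_equals_p_keeps_all():
    rng = np.random.default_rng(2)
    c = _cohort_from(rng.integers(0, 3, (30, 8)), rng.integers(0, 2, 30), rng.integers(0, 2, 30).astype(float))
    res = prescreen(c, "marginal", 8)
    assert sorted(res.kept_indices) == list(range(8))


def test_k_out_of_range_errors():
    rng = np.random.default_rng(3)
    c = _cohort_from(rng.integers(0, 3, (10, 4)), rng.integers(0, 2, 10), rng.integers(0, 2, 10).astype(float))
    with pytest.raises(ParameterError):
        prescreen(c, "marginal", 5)
    with pytest.raises(ParameterError):
        prescreen(c, "sideways", 2)


def test_correlation_filter_targets_exposure():
    rng = np.random.default_rng(4)
    G = rng.integers(0, 3, (200, 5))
    E = (G[:, 2] > 0).astype(float)  # exposure tracks marker 2
    y = rng.integers(0, 2, 200)
    res = prescreen(_cohort_from(G, y, E), "correlation", 1)
    assert res.kept_indices[0] == 2
    assert res.target_kind == "exposure"


def test_kept_set_matches_bruteforce_on_simulated_cohort():
    # Exact integer arithmetic oracle: n * score_j = |n*sum(y G) - sum(y) sum(G)|.
    # Ties are frequent among null SNPs, so the kept sets are compared through
    # their (exact) score multisets rather than by index order.
    from spurgxe import make_null_design, simulate_cohort

    cohort = simulate_cohort(make_null_design(n_subjects=300, n_snps=120), seed=5)
    res = prescreen(cohort, "marginal", 30)
    y = cohort.outcome.astype(np.int64)
    G = cohort.genotypes.astype(np.int64)
    exact = np.abs(len(y) * (y @ G) - y.sum() * G.sum(axis=0))
    oracle_kept = np.argsort(-exact, kind="stable")[:30]
    assert sorted(exact[res.kept_indices]) == sorted(exact[oracle_kept])
    # the boundary score is respected: nothing outside beats anything inside
    outside = np.setdiff1d(np.arange(120), res.kept_indices)
    assert exact[outside].max() <= exact[res.kept_indices].min()
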