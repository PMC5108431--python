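"""Tests of BH adjustment and the two-level hierarchical FDR procedure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spurgxe import bh_adjust, effective_fdr_level, hierarchical_fdr


def brute_force_bh(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        j = order[rank - 1]
        running = min(running, p[j] * m / rank)
        adj[j] = min(running, 1.0)
    return adj


def test_hand_stepup_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
    )


def test_single_and_equal_pvalues():
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(bh_adjust([0.04, 0.04, 0.04]), [0.04] * 3, atol=1e-12)


def test_out_of_range_rejected():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.3])


def test_nan_excluded_from_family_size():
    adj = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(adj[1])
    # family size is 2, not 3
    np.testing.assert_allclose(adj[[0, 2]], brute_force_bh([0.01, 0.04]), atol=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20))
def test_matches_bruteforce_stepup(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=15),
    st.randoms(use_true_random=False),
)
def test_permutation_equivariance_and_monotonicity(pvals, rnd):
    p = np.asarray(pvals)
    perm = np.arange(len(p))
    rnd.shuffle(perm)
    adj = bh_adjust(p)
    np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_effective_level_worked_example():
    assert effective_fdr_level(0.1, f=2, d=4) == pytest.approx(0.12)
    # a single family reduces to plain BH level
    for d in (0, 3, 17):
        assert effective_fdr_level(0.07, f=1, d=d) == pytest.approx(0.07)
    assert effective_fdr_level(0.05, f=3, d=2) == pytest.approx(0.05 * 5 / 3)


def test_effective_level_validation():
    with pytest.raises(ValueError):
        effective_fdr_level(0.1, f=0, d=0)
    with pytest.raises(ValueError):
        effective_fdr_level(0.1, f=1, d=-1)


def test_hierarchy_worked_example_level():
    # two filter families, four child discoveries at q=0.1 -> 0.12
    res = hierarchical_fdr(
        [0.001, 0.002],
        [np.array([0.001, 0.004, 0.9]), np.array([0.002, 0.01, 0.8])],
        q=0.1,
    )
    assert res.discoveries == 4
    assert res.effective_level == pytest.approx(0.12)


def test_children_only_opened_under_rejected_parents():
    res = hierarchical_fdr([0.001, 0.9], [np.array([0.01]), np.array([0.001])], q=0.1)
    assert res.rejected_parents.tolist() == [True, False]
    assert res.child_qvalues[1] is None
    assert res.discoveries == 1


def test_no_child_rejections_gives_qf_level():
    res = hierarchical_fdr([0.001], [np.array([1.0, 1.0, 1.0])], q=0.1)
    assert res.discoveries == 0
    assert res.effective_level == pytest.approx(0.1)


def test_single_family_matches_flat_bh():
    rng = np.random.default_rng(0)
    fam = rng.random(12) ** 2
    res = hierarchical_fdr([1e-6], [fam], q=0.1)
    flat = bh_adjust(fam)
    np.testing.assert_allclose(res.child_qvalues[0], flat, atol=1e-12)
    assert np.array_equal(res.child_rejected[0], flat <= 0.1)


def test_empty_parents_rejected():
    with pytest.raises(ValueError):
        hierarchical_fdr([], [], q=0.1)
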