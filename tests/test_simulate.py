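"""Tests of the synthetic cohort generator."""

import numpy as np
import pytest
from scipy.special import expit

from spurgxe import (
    ParameterError,
    SimulationDesign,
    make_null_design,
    make_power_design,
    realized_genotype_correlation,
    realized_genotype_exposure_correlation,
    sample_case_control,
    simulate_cohort,
    simulate_exposure,
    simulate_genotypes,
    simulate_outcome,
)

N_BIG = 50_000


@pytest.mark.parametrize("maf", [0.05, 0.2, 0.45])
def test_genotype_marginals_match_hwe(maf):
    G = simulate_genotypes(N_BIG, 4, maf, 0.0, seed=1)
    expected = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    for g, p in enumerate(expected):
        freq = (G == g).mean()
        se = np.sqrt(p * (1 - p) / (N_BIG * 4))
        assert abs(freq - p) < 3 * se + 1e-4


def test_independent_columns_when_rho_zero():
    G = simulate_genotypes(N_BIG, 10, 0.2, 0.0, seed=2)
    c = np.corrcoef(G.T)
    off = c[np.triu_indices(10, 1)]
    assert np.abs(off).max() < 0.02


def test_latent_correlation_attenuates_to_analytic_value():
    # The exchangeable latent rho is attenuated by HWE thresholding; the
    # realized genotype correlation must match the thresholded-BVN oracle.
    analytic = realized_genotype_correlation(0.2, 0.1)
    assert 0.06 < analytic < 0.075  # regression constant, ~0.0675
    G = simulate_genotypes(N_BIG, 10, 0.2, 0.1, seed=3)
    c = np.corrcoef(G.T)
    off = c[np.triu_indices(10, 1)]
    assert abs(off.mean() - analytic) < 0.008
    assert off.mean() > 0


def test_exposure_independent_without_designated_snps():
    design = SimulationDesign(n_subjects=N_BIG, n_snps=8, snp_exposure_corr={})
    G = simulate_genotypes(N_BIG, 8, 0.2, 0.1, seed=4)
    E = simulate_exposure(G, design, seed=5)
    assert abs(E.mean() - 0.5) < 0.01
    r = [abs(np.corrcoef(G[:, j], E)[0, 1]) for j in range(8)]
    assert max(r) < 0.02


@pytest.mark.parametrize("target", [0.05, 0.3])
def test_exposure_correlation_matches_attenuated_target(target):
    # Latent-scale targets; realized correlation equals the analytic
    # thresholded value (about 0.65 * target at MAF 0.2, Bernoulli(0.5)).
    design = SimulationDesign(
        n_subjects=N_BIG,
        n_snps=15,
        snp_exposure_corr={j: target for j in range(5)},
    )
    cohort = simulate_cohort(design, seed=6)
    expected = realized_genotype_exposure_correlation(0.2, 0.5, target)
    for j in range(5):
        r = np.corrcoef(cohort.genotypes[:, j], cohort.exposure)[0, 1]
        assert abs(r - expected) < 0.02
    for j in range(5, 10):
        r = np.corrcoef(cohort.genotypes[:, j], cohort.exposure)[0, 1]
        assert abs(r) < 0.02


def test_infeasible_exposure_targets_rejected():
    with pytest.raises(ParameterError):
        SimulationDesign(
            n_subjects=100, n_snps=10,
            snp_exposure_corr={j: 0.5 for j in range(10)},
        )


def test_outcome_prevalence_logistic():
    design = SimulationDesign(n_subjects=N_BIG, n_snps=5, beta0=0.0, betaE=0.0)
    G = simulate_genotypes(N_BIG, 5, 0.2, 0.0, seed=7)
    E = np.zeros(N_BIG)
    y = simulate_outcome(G, E, design, seed=8)
    assert abs(y.mean() - 0.5) < 0.01
    design2 = SimulationDesign(n_subjects=N_BIG, n_snps=5, beta0=-4.0, betaE=0.0)
    y2 = simulate_outcome(G, E, design2, seed=9)
    assert abs(y2.mean() - expit(-4.0)) < 0.004


def test_null_design_case_fraction_regression_constant():
    # frozen from a large-n draw of the null study design
    cohort = simulate_cohort(make_null_design(n_subjects=N_BIG), seed=10)
    assert abs(cohort.outcome.mean() - 0.134) < 0.012


def test_prevalence_monotone_in_intercept():
    G = simulate_genotypes(20_000, 3, 0.2, 0.0, seed=11)
    E = np.zeros(20_000)
    fractions = []
    for b0 in (-3.0, -1.0, 1.0):
        d = SimulationDesign(n_subjects=20_000, n_snps=3, beta0=b0, betaE=0.0)
        fractions.append(simulate_outcome(G, E, d, seed=12).mean())
    assert fractions[0] < fractions[1] < fractions[2]


def test_null_design_structure():
    d = make_null_design()
    assert d.n_subjects == 1000 and d.n_snps == 2000
    assert d.maf == 0.2 and d.snp_snp_corr == 0.1
    assert np.all(d.betaGE == 0)
    assert set(np.flatnonzero(d.betaG)) == set(range(10))
    assert np.allclose(d.betaG[:10], np.log(1.5))
    assert d.snp_exposure_corr == {j: 0.05 for j in range(10)}


@pytest.mark.parametrize("model", [1, 2])
def test_power_design_structure(model):
    d = make_power_design(model)
    assert set(np.flatnonzero(d.betaGE)) == set(range(5))
    assert np.allclose(d.betaGE[:5], np.log(3.0))
    if model == 1:
        assert set(np.flatnonzero(d.betaG)) == set(range(5))
        assert set(d.snp_exposure_corr) == set(range(5, 10))
    else:
        assert set(np.flatnonzero(d.betaG)) == set(range(5, 10))
        assert np.allclose(d.betaG[5:10], np.log(3.0))
        assert set(d.snp_exposure_corr) == set(range(5))
    assert all(v == 0.3 for v in d.snp_exposure_corr.values())


def test_sample_case_control_exhaustive_and_exact():
    d = SimulationDesign(n_subjects=20, n_snps=4, beta0=0.0)
    pool = simulate_cohort(d, seed=13)
    n_cases = int(pool.outcome.sum())
    n_controls = 20 - n_cases
    out = sample_case_control(pool, n_cases, n_controls, seed=14)
    assert out.n_subjects == 20
    assert sorted(map(tuple, out.genotypes)) == sorted(map(tuple, pool.genotypes))

    big = simulate_cohort(SimulationDesign(n_subjects=5000, n_snps=4, beta0=0.0), seed=15)
    cc = sample_case_control(big, 500, 500, seed=16)
    assert cc.outcome.mean() == 0.5


def test_sample_case_control_deficit_error():
    d = SimulationDesign(n_subjects=50, n_snps=3, beta0=-6.0)
    pool = simulate_cohort(d, seed=17)
    with pytest.raises(ParameterError, match="short by"):
        sample_case_control(pool, 49, 1, seed=18)


def test_bit_reproducibility():
    d = make_power_design(1, n_subjects=200, n_snps=30)
    a = simulate_cohort(d, seed=99)
    b = simulate_cohort(d, seed=99)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert np.array_equal(a.exposure, b.exposure)
    assert np.array_equal(a.outcome, b.outcome)


def test_invalid_parameters():
    with pytest.raises(ParameterError):
        simulate_genotypes(10, 2, 0.7, 0.0)
    with pytest.raises(ParameterError):
        simulate_genotypes(10, 2, 0.2, 1.5)
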