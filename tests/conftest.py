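import numpy as np
import pytest

from spurgxe import Cohort, SimulationDesign, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest power-style cohort: 400 subjects x 60 SNPs, 3 true interactions."""
    betaG = np.zeros(60)
    betaGE = np.zeros(60)
    betaG[:3] = np.log(1.5)
    betaGE[:3] = np.log(3.0)
    design = SimulationDesign(
        n_subjects=400,
        n_snps=60,
        beta0=-1.0,
        betaG=betaG,
        betaGE=betaGE,
        snp_exposure_corr={},
    )
    return simulate_cohort(design, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A deterministic 8-subject cohort for exact IO round-trips."""
    return Cohort(
        genotypes=np.array(
            [
                [0, 1], [1, 2], [2, 0], [0, 0],
                [1, 1], [2, 2], [0, 1], [1, 0],
            ]
        ),
        exposure=np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=float),
        outcome=np.array([0, 1, 0, 0, 1, 1, 0, 1]),
        covariates=np.array(
            [[52.0], [61.0], [48.0], [55.0], [70.0], [66.0], [59.0], [63.0]]
        ),
        marker_ids=["rs1", "rs2"],
        exposure_kind="binary",
    )
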