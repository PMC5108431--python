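"""Synthetic case-control cohorts for G×E interaction studies.

Genotypes are generated from a latent exchangeable Gaussian copula: each
SNP's latent coordinate is ``z_j = sqrt(rho) * f + sqrt(1 - rho) * e_j`` for
a shared factor ``f``, then thresholded at the Hardy-Weinberg quantiles
``Phi^-1((1-maf)^2)`` and ``Phi^-1(1-maf^2)`` to additive genotype counts
{0, 1, 2}.  This preserves the HWE genotype marginals exactly while giving
every SNP pair latent correlation ``rho``.  The realized (Pearson)
correlation between thresholded genotype columns is smaller than ``rho`` —
about 0.66*rho at MAF 0.2 — and :func:`realized_genotype_correlation`
computes the exact value.

The environmental exposure is one more coordinate of the latent Gaussian.
A designated set of SNPs S receives latent correlation ``r_j`` with the
exposure coordinate by loading it on the SNPs' idiosyncratic components:

    w = sum_{j in S} (r_j / sqrt(1 - rho)) * e_j + gamma_u * u

which gives corr(w, z_j) = r_j exactly for designated SNPs and exactly 0
for all others.  Binary exposures threshold ``w`` at
``Phi^-1(1 - exposure_prob)``; continuous exposures use ``w`` itself
(exactly standard normal).  Correlation targets refer to the latent scale;
the realized genotype-exposure correlation is attenuated by thresholding
in the same way as the genotype-genotype correlation (about 0.65 * r at
MAF 0.2 with a Bernoulli(0.5) exposure; exact value from
:func:`realized_genotype_exposure_correlation`).  The latent reading keeps
the joint dependence of the exposure on the designated SNP set minimal
(jointly Gaussian, R-squared = sum r_j^2 / (1 - rho)); forcing the
*realized* pairwise correlations to equal the targets while keeping zero
correlation with all other SNPs is either infeasible (not positive
definite) or requires concentrating far more joint SNP-set signal in the
exposure than the stated pairwise parameters suggest.

The binary outcome follows a logistic model with marginal SNP effects and
SNP-exposure interaction effects on the log-odds scale:

    logit P(D=1) = beta0 + betaE*E + sum_j betaG_j*G_j + sum_j betaGE_j*G_j*E
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, ndtri
from scipy.stats import multivariate_normal, norm

from .cohort import Cohort, ParameterError

__all__ = [
    "SimulationDesign",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_outcome",
    "simulate_cohort",
    "make_null_design",
    "make_power_design",
    "sample_case_control",
    "realized_genotype_correlation",
    "realized_genotype_exposure_correlation",
]

LOG_1_5 = math.log(1.5)
LOG_3 = math.log(3.0)


@dataclass
class SimulationDesign:
    """Full parameterization of a simulated case-control cohort.

    ``snp_exposure_corr`` maps 0-based marker indices to latent-scale
    correlation targets between the exposure coordinate and that SNP's
    latent Gaussian coordinate (see module docstring).
    ``betaG`` / ``betaGE`` are length-``n_snps`` log-odds coefficient vectors
    for marginal and interaction effects.
    """

    n_subjects: int = 1000
    n_snps: int = 2000
    maf: float = 0.2
    snp_snp_corr: float = 0.1
    exposure_kind: str = "binary"
    exposure_prob: float = 0.5
    snp_exposure_corr: dict[int, float] = field(default_factory=dict)
    beta0: float = -4.0
    betaE: float = LOG_1_5
    betaG: np.ndarray | None = None
    betaGE: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.betaG is None:
            self.betaG = np.zeros(self.n_snps)
        if self.betaGE is None:
            self.betaGE = np.zeros(self.n_snps)
        self.betaG = np.asarray(self.betaG, dtype=float)
        self.betaGE = np.asarray(self.betaGE, dtype=float)
        if self.betaG.shape != (self.n_snps,) or self.betaGE.shape != (self.n_snps,):
            raise ParameterError("betaG/betaGE length must equal n_snps")
        if not 0.0 < self.maf <= 0.5:
            raise ParameterError(f"maf must be in (0, 0.5], got {self.maf}")
        if not 0.0 <= self.snp_snp_corr < 1.0:
            raise ParameterError(
                f"snp_snp_corr must be in [0, 1), got {self.snp_snp_corr}"
            )
        if self.exposure_kind not in ("binary", "continuous"):
            raise ParameterError(f"unknown exposure_kind {self.exposure_kind!r}")
        if not 0.0 < self.exposure_prob < 1.0:
            raise ParameterError("exposure_prob must be in (0, 1)")
        for j, r in self.snp_exposure_corr.items():
            if not 0 <= j < self.n_snps:
                raise ParameterError(f"snp_exposure_corr index {j} out of range")
            if not -1.0 < r < 1.0:
                raise ParameterError(f"snp_exposure_corr[{j}]={r} outside (-1, 1)")
        if self.snp_exposure_corr:
            # raises ParameterError if the targets are unattainable or the
            # exposure index's variance budget is exceeded
            _exposure_loadings(self)

    def with_seed(self, seed: int | None) -> "SimulationDesign":
        return replace(self, seed=seed)


def _hwe_thresholds(maf: float) -> tuple[float, float]:
    return ndtri((1.0 - maf) ** 2), ndtri(1.0 - maf**2)


def _threshold_genotypes(z: np.ndarray, maf: float) -> np.ndarray:
    t1, t2 = _hwe_thresholds(maf)
    return ((z > t1).astype(np.int8) + (z > t2).astype(np.int8))


def simulate_genotypes(
    n: int, p: int, maf: float, rho: float, seed=None
) -> np.ndarray:
    """Draw an (n, p) additive-coded genotype matrix.

    Marginals are exactly HWE at the given MAF; ``rho`` is the latent
    exchangeable pairwise correlation (realized genotype correlation is
    attenuated, see module docstring).
    """
    if not 0.0 < maf <= 0.5:
        raise ParameterError(f"maf must be in (0, 0.5], got {maf}")
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    e = rng.standard_normal((n, p))
    z = math.sqrt(rho) * f[:, None] + math.sqrt(1.0 - rho) * e
    return _threshold_genotypes(z, maf)


def _exposure_loadings(design: SimulationDesign):
    """Loadings of the exposure's latent coordinate on the designated SNPs'
    idiosyncratic components; raises if the variance budget is exceeded."""
    idx = sorted(design.snp_exposure_corr)
    rho = design.snp_snp_corr
    targets = np.array([design.snp_exposure_corr[j] for j in idx])
    if np.any(np.abs(targets) >= math.sqrt(1.0 - rho)):
        raise ParameterError(
            "a snp_exposure_corr target exceeds the attainable latent bound "
            f"sqrt(1 - rho) = {math.sqrt(1.0 - rho):.3f}"
        )
    gamma = targets / math.sqrt(1.0 - rho)
    resid_var = 1.0 - float(gamma @ gamma)
    if resid_var < 0.0:
        raise ParameterError(
            "snp_exposure_corr targets are jointly infeasible: latent loading "
            f"variance {float(gamma @ gamma):.3f} > 1"
        )
    return idx, gamma, math.sqrt(resid_var)


def _finish_exposure(w: np.ndarray, design: SimulationDesign) -> np.ndarray:
    if design.exposure_kind == "binary":
        return (w > ndtri(1.0 - design.exposure_prob)).astype(float)
    return w


def simulate_exposure(
    genotypes: np.ndarray,
    design: SimulationDesign,
    seed=None,
    latent_residuals: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an exposure vector with target latent correlations to the
    designated SNPs' coordinates.

    When called from :func:`simulate_cohort` the designated SNPs' latent
    residuals are available and the construction is exact (zero correlation
    with all non-designated SNPs).  When only a genotype matrix is supplied,
    latent coordinates consistent with the observed genotypes are
    reconstructed by sampling truncated normals within each genotype's HWE
    band; this reconstruction cannot subtract the shared SNP factor, so with
    ``snp_snp_corr > 0`` non-designated SNPs may pick up a small spillover
    correlation.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.shape[0]
    idx = sorted(design.snp_exposure_corr)
    if len(idx) == 0:
        if design.exposure_kind == "binary":
            return (rng.random(n) < design.exposure_prob).astype(float)
        return rng.standard_normal(n)
    if latent_residuals is not None:
        _, gamma, gamma_u = _exposure_loadings(design)
        w = latent_residuals[:, idx] @ gamma + gamma_u * rng.standard_normal(n)
        return _finish_exposure(w, design)
    # Reconstruct latent coordinates consistent with the observed genotypes.
    t1, t2 = _hwe_thresholds(design.maf)
    cum = np.array([0.0, norm.cdf(t1), norm.cdf(t2), 1.0])
    zhat = np.empty((n, len(idx)))
    for col, j in enumerate(idx):
        g = np.asarray(genotypes[:, j], dtype=int)
        lo, hi = cum[g], cum[g + 1]
        zhat[:, col] = ndtri(lo + rng.random(n) * (hi - lo))
    targets = np.array([design.snp_exposure_corr[j] for j in idx])
    cov = np.corrcoef(zhat, rowvar=False)
    cov = np.atleast_2d(cov)
    gamma = np.linalg.solve(cov, targets)
    explained = float(targets @ gamma)
    if explained > 1.0:
        raise ParameterError(
            "snp_exposure_corr targets infeasible for these genotypes "
            f"(explained variance {explained:.3f} > 1)"
        )
    zhat = (zhat - zhat.mean(0)) / zhat.std(0)
    w = zhat @ gamma + math.sqrt(1.0 - explained) * rng.standard_normal(n)
    return _finish_exposure(w, design)


def simulate_outcome(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    design: SimulationDesign,
    seed=None,
) -> np.ndarray:
    """Bernoulli outcome from the logistic G/E/G×E model."""
    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes, dtype=float)
    if g.shape[1] != design.n_snps:
        raise ParameterError(
            f"genotype matrix has {g.shape[1]} markers, design expects {design.n_snps}"
        )
    eta = (
        design.beta0
        + design.betaE * exposure
        + g @ design.betaG
        + (g * exposure[:, None]) @ design.betaGE
    )
    return (rng.random(len(eta)) < expit(eta)).astype(int)


def simulate_cohort(design: SimulationDesign, seed=None) -> Cohort:
    """Generate a full cohort (genotypes, exposure, outcome) from a design.

    With a fixed seed the draw is bit-reproducible.  ``seed`` overrides
    ``design.seed`` when given.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    n, p = design.n_subjects, design.n_snps
    rho = design.snp_snp_corr
    f = rng.standard_normal(n)
    e = rng.standard_normal((n, p))
    z = math.sqrt(rho) * f[:, None] + math.sqrt(1.0 - rho) * e
    genotypes = _threshold_genotypes(z, design.maf)
    if design.snp_exposure_corr:
        exposure = simulate_exposure(genotypes, design, seed=rng, latent_residuals=e)
    else:
        if design.exposure_kind == "binary":
            exposure = (rng.random(n) < design.exposure_prob).astype(float)
        else:
            exposure = rng.standard_normal(n)
    outcome = simulate_outcome(genotypes, exposure, design, rng)
    return Cohort(
        genotypes=genotypes,
        exposure=exposure,
        outcome=outcome,
        exposure_kind=design.exposure_kind,
    )


def make_null_design(
    n_subjects: int = 1000, n_snps: int = 2000, seed: int | None = None
) -> SimulationDesign:
    """Type-I-error study design: no interactions anywhere.

    The first 10 SNPs carry a marginal log-odds effect of log(1.5) and a
    latent exposure correlation of 0.05; the exposure is Bernoulli(0.5).
    """
    betaG = np.zeros(n_snps)
    betaG[: min(10, n_snps)] = LOG_1_5
    corr = {j: 0.05 for j in range(min(10, n_snps))}
    return SimulationDesign(
        n_subjects=n_subjects,
        n_snps=n_snps,
        maf=0.2,
        snp_snp_corr=0.1,
        exposure_kind="binary",
        exposure_prob=0.5,
        snp_exposure_corr=corr,
        beta0=-4.0,
        betaE=LOG_1_5,
        betaG=betaG,
        betaGE=np.zeros(n_snps),
        seed=seed,
    )


def make_power_design(
    model: int, n_subjects: int = 1000, n_snps: int = 2000, seed: int | None = None
) -> SimulationDesign:
    """Power study designs with true interactions on the first five SNPs.

    Model 1 favors the marginal-association filter: SNPs 1-5 carry both the
    interaction (log 3) and a marginal effect (log 1.5), while only SNPs
    6-10 are exposure-correlated (latent 0.3).  Model 2 favors the
    gene-environment-correlation filter: SNPs 1-5 carry the interaction and
    the exposure correlation (latent 0.3), while SNPs 6-10 carry a marginal
    effect of log 3 and no interaction.
    """
    if model not in (1, 2):
        raise ParameterError(f"model must be 1 or 2, got {model}")
    if n_snps < 10:
        raise ParameterError("power designs need at least 10 SNPs")
    betaG = np.zeros(n_snps)
    betaGE = np.zeros(n_snps)
    betaGE[:5] = LOG_3
    if model == 1:
        betaG[:5] = LOG_1_5
        corr = {j: 0.3 for j in range(5, 10)}
    else:
        betaG[5:10] = LOG_3
        corr = {j: 0.3 for j in range(5)}
    return SimulationDesign(
        n_subjects=n_subjects,
        n_snps=n_snps,
        maf=0.2,
        snp_snp_corr=0.1,
        exposure_kind="binary",
        exposure_prob=0.5,
        snp_exposure_corr=corr,
        beta0=-4.0,
        betaE=LOG_1_5,
        betaG=betaG,
        betaGE=betaGE,
        seed=seed,
    )


def sample_case_control(
    pool: Cohort, n_cases: int, n_controls: int, seed=None
) -> Cohort:
    """Sample a fixed-size case-control study from a population pool.

    Cases and controls are drawn without replacement; the returned cohort
    has exactly ``n_cases`` subjects with outcome 1 and ``n_controls`` with
    outcome 0, in randomly permuted order.
    """
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(pool.outcome == 1)
    controls = np.flatnonzero(pool.outcome == 0)
    if len(cases) < n_cases:
        raise ParameterError(
            f"pool has {len(cases)} cases, {n_cases} requested "
            f"(short by {n_cases - len(cases)})"
        )
    if len(controls) < n_controls:
        raise ParameterError(
            f"pool has {len(controls)} controls, {n_controls} requested "
            f"(short by {n_controls - len(controls)})"
        )
    chosen = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    rng.shuffle(chosen)
    return pool.subset(chosen)


# -- analytic oracles for the thresholded-Gaussian construction ---------------

def _bvn_sf(a: float, b: float, r: float) -> float:
    """P(Z1 > a, Z2 > b) for standard bivariate normal with correlation r."""
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    return 1.0 - norm.cdf(a) - norm.cdf(b) + float(mvn.cdf([a, b]))


def realized_genotype_correlation(maf: float, rho: float) -> float:
    """Exact Pearson correlation between two thresholded genotype columns
    whose latent coordinates have correlation ``rho``."""
    t1, t2 = _hwe_thresholds(maf)
    egg = sum(_bvn_sf(a, b, rho) for a in (t1, t2) for b in (t1, t2))
    mean_g = 2.0 * maf
    var_g = 2.0 * maf * (1.0 - maf)
    return (egg - mean_g**2) / var_g


def realized_genotype_exposure_correlation(
    maf: float, exposure_prob: float, latent_r: float
) -> float:
    """Exact Pearson correlation between a thresholded genotype column and a
    binary exposure whose latent coordinates have correlation ``latent_r``."""
    t1, t2 = _hwe_thresholds(maf)
    c = ndtri(1.0 - exposure_prob)
    ege = sum(_bvn_sf(a, c, latent_r) for a in (t1, t2))
    cov = ege - 2.0 * maf * exposure_prob
    sd_g = math.sqrt(2.0 * maf * (1.0 - maf))
    sd_e = math.sqrt(exposure_prob * (1.0 - exposure_prob))
    return cov / (sd_g * sd_e)
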