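"""Synthetic individual-level MR data with LD and pleiotropy.

Genotypes are generated by a Gaussian copula: latent multivariate-normal
vectors with a Toeplitz correlation matrix (entry ``rho_g**|j1 - j2|``) are
pushed through the standard-normal CDF and mapped to Binomial(2, MAF_j)
dosages by the inverse CDF.  This gives Hardy-Weinberg marginals at each
locus while the Toeplitz structure induces LD that decays with the distance
between loci and strengthens with ``rho_g``.

Phenotypes follow the structural model

    X = G gamma + eps_X,
    Y = G alpha + X beta + eps_Y,

with ``alpha ~ N(mu_alpha 1, sigma_alpha^2 I)`` the random pleiotropic
effect and ``(eps_X, eps_Y)`` bivariate normal per individual with
correlation ``rho`` — the entire influence of unmeasured confounders is
carried by that error correlation.

Reproducibility: one seeded generator drives each replicate, consumed in a
fixed stream order (MAF draw, copula normals, gamma, alpha, errors), so a
given (config, seed) pair yields a bit-identical dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .model_core import GenotypeMatrix, PhenotypePair, center_columns

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "toeplitz_sigma",
    "gen_genotypes",
    "gen_phenotypes",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation scenario.

    Defaults are the package's reference simulation design:
    MAF_j ~ U[0.2, 0.4], gamma_j ~ U[0.5, 4], sigma_X = sigma_Y = 2,
    confounder correlation rho = 0.5, m = 25 instruments, nominal test
    level 0.05.
    """

    n: int = 5000
    m: int = 25
    rho_g: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.1
    beta: float = 0.0
    sigma_x: float = 2.0
    sigma_y: float = 2.0
    rho: float = 0.5
    maf_low: float = 0.2
    maf_high: float = 0.4
    gamma_low: float = 0.5
    gamma_high: float = 4.0
    n_reps: int = 2000
    seed: int = 0
    alpha_level: float = 0.05
    #: redraw MAF_j and gamma_j each replicate (True) or fix them once per
    #: scenario (False)
    redraw_per_replicate: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.rho_g < 1):
            raise ValueError("rho_g must lie in [0, 1)")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must lie in (-1, 1)")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.gamma_low > self.gamma_high:
            raise ValueError("gamma_low must not exceed gamma_high")
        if not (self.n > self.m >= 3):
            raise ValueError("need n > m >= 3")
        if self.sigma_alpha < 0 or self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_alpha >= 0 and sigma_x, sigma_y > 0 required")
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    """One simulated cohort plus the generating truth."""

    genotypes: GenotypeMatrix  # raw dosages, uncentered
    phenotypes: PhenotypePair  # raw X, Y (centered downstream)
    truth: dict = field(default_factory=dict)


def toeplitz_sigma(m: int, rho_g: float) -> np.ndarray:
    """Toeplitz latent-correlation matrix with entries rho_g**|j1 - j2|.

    Symmetric with unit diagonal; positive definite for rho_g in [0, 1)
    (it is the autocorrelation matrix of an AR(1) process).
    """
    if not (0 <= rho_g < 1):
        raise ValueError(f"rho_g must lie in [0, 1), got {rho_g}")
    idx = np.arange(m)
    return rho_g ** np.abs(idx[:, None] - idx[None, :])


def gen_genotypes(
    n: int,
    m: int,
    rho_g: float,
    mafs: np.ndarray,
    rng: np.random.Generator,
    max_redraws: int = 20,
) -> GenotypeMatrix:
    """Draw an n x m additive genotype matrix via the Gaussian copula.

    Latent vectors z_i ~ MVN(0, Sigma_g) with the Toeplitz correlation are
    transformed to uniforms by the standard-normal CDF; the dosage is the
    smallest k in {0, 1, 2} whose Binomial(2, MAF_j) CDF reaches that
    uniform.  A whole-matrix redraw (preserving the LD structure) is
    triggered if any sampled column comes out monomorphic; this is only
    plausible at small n * MAF and is logged when it happens.
    """
    mafs = np.asarray(mafs, dtype=float).ravel()
    if mafs.shape[0] != m:
        raise ValueError("need one MAF per variant")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    sigma = toeplitz_sigma(m, rho_g)
    chol = np.linalg.cholesky(sigma)
    # Binomial(2, p) CDF breakpoints under Hardy-Weinberg
    c0 = (1.0 - mafs) ** 2
    c1 = 1.0 - mafs**2
    for attempt in range(max_redraws):
        z = rng.standard_normal((n, m)) @ chol.T
        u = ndtr(z)
        dosages = (u > c0).astype(float) + (u > c1)
        if np.all(dosages.std(axis=0) > 0):
            break
        logger.info("monomorphic column sampled (attempt %d); redrawing", attempt + 1)
    else:
        raise RuntimeError(
            f"could not draw a polymorphic genotype matrix in {max_redraws} attempts"
        )
    return GenotypeMatrix(dosages, centered=False)


def gen_phenotypes(
    G: GenotypeMatrix,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    gammas: Optional[np.ndarray] = None,
    mafs: Optional[np.ndarray] = None,
) -> SimulatedDataset:
    """Generate (X, Y) from the structural model on top of given genotypes.

    Stream order on ``rng``: gamma (unless supplied), alpha, then the
    bivariate errors.  The genotype matrix is centered before entering the
    model so that the recorded coefficients refer to centered dosages.
    """
    Gc = center_columns(G.values) if not G.centered else G.values
    n, m = Gc.shape
    if gammas is None:
        gammas = rng.uniform(cfg.gamma_low, cfg.gamma_high, size=m)
    else:
        gammas = np.asarray(gammas, dtype=float).ravel()
    alpha = cfg.mu_alpha + cfg.sigma_alpha * rng.standard_normal(m)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eps_x = cfg.sigma_x * z1
    eps_y = cfg.sigma_y * (cfg.rho * z1 + np.sqrt(1.0 - cfg.rho**2) * z2)
    x = Gc @ gammas + eps_x
    y = Gc @ alpha + x * cfg.beta + eps_y
    truth = {
        "gamma": gammas.tolist(),
        "alpha": alpha.tolist(),
        "beta": cfg.beta,
        "mu_alpha": cfg.mu_alpha,
        "sigma_alpha2": cfg.sigma_alpha**2,
        "sigma_x2": cfg.sigma_x**2,
        "sigma_y2": cfg.sigma_y**2,
        "rho": cfg.rho,
        "maf": None if mafs is None else np.asarray(mafs).tolist(),
    }
    return SimulatedDataset(
        genotypes=G,
        phenotypes=PhenotypePair(x, y),
        truth=truth,
    )


def simulate_dataset(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    mafs: Optional[np.ndarray] = None,
    gammas: Optional[np.ndarray] = None,
) -> SimulatedDataset:
    """One full replicate: MAFs, genotypes, then phenotypes, from one stream.

    ``mafs``/``gammas`` may be supplied to hold them fixed across replicates
    (the ``redraw_per_replicate=False`` scenario mode).
    """
    if mafs is None:
        mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.m)
    G = gen_genotypes(cfg.n, cfg.m, cfg.rho_g, mafs, rng)
    return gen_phenotypes(G, cfg, rng, gammas=gammas, mafs=mafs)
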