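"""Core domain types and the shared linear-algebra layer.

Everything downstream (estimators, simulation harness, CLI) works with the
types defined here: a centered genotype matrix, a centered exposure/outcome
pair, the joint (multiple-regression) coefficient estimates with the cached
eigendecomposition of the inverse Gram matrix, the per-variant marginal
coefficients, and the variance components of the mixed-effects pleiotropy
model.

Conventions
-----------
* All regressions run on centered data and are fit *without* an intercept;
  centering absorbs it.
* The Gram matrix is ``S = G'G`` of the centered genotypes.  Its inverse is
  eigendecomposed once per dataset as ``S^{-1} = Q diag(lam) Q'`` and cached,
  with eigenvalues sorted in descending order and a deterministic sign
  convention (first non-negligible entry of each eigenvector is positive).
* Ill-conditioned Gram matrices (condition number above ``COND_MAX``) are
  rejected with an error naming the most collinear columns rather than being
  silently regularized: LD pruning is the user's modelling decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PhenotypePair",
    "JointCoefs",
    "MarginalCoefs",
    "VarianceComponents",
    "RankDeficiencyError",
    "center_columns",
    "joint_coefs",
    "marginal_coefs",
    "weight_matrix",
    "weight_matrix_dense",
]

#: Gram matrices with condition number above this are rejected.
COND_MAX = 1e12


class RankDeficiencyError(ValueError):
    """Raised when the genotype Gram matrix is singular or ill-conditioned."""


@dataclass
class GenotypeMatrix:
    """An n x m additive-dosage genotype matrix with sample/variant labels.

    Raw entries live in {0, 1, 2}; after :meth:`center` every column has
    zero mean.  Monomorphic (zero-variance) columns are rejected because no
    regression coefficient is identifiable for them.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if not self.variant_ids:
            self.variant_ids = [f"snp_{j}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise ValueError("label lengths do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains missing/non-finite entries")
        sd = self.values.std(axis=0)
        if np.any(sd == 0.0):
            bad = [self.variant_ids[j] for j in np.flatnonzero(sd == 0.0)]
            raise ValueError(f"monomorphic (zero-variance) variants: {bad}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def center(self) -> "GenotypeMatrix":
        """Return a column-centered copy (no-op if already centered)."""
        if self.centered:
            return self
        return GenotypeMatrix(
            center_columns(self.values),
            sample_ids=list(self.sample_ids),
            variant_ids=list(self.variant_ids),
            centered=True,
        )


@dataclass
class PhenotypePair:
    """Centered exposure (X) and outcome (Y) vectors for the same samples."""

    exposure: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=float).ravel()
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        if self.exposure.shape != self.outcome.shape:
            raise ValueError("exposure and outcome lengths differ")

    @property
    def n(self) -> int:
        return self.exposure.shape[0]

    def center(self) -> "PhenotypePair":
        return PhenotypePair(
            self.exposure - self.exposure.mean(),
            self.outcome - self.outcome.mean(),
        )


@dataclass
class JointCoefs:
    """Multiple-regression coefficients with the cached Gram eigensystem.

    ``gamma_hat`` and ``Gamma_hat`` are the coefficient vectors of the
    multiple regression of the exposure and the outcome on all variants
    jointly; ``gram`` is ``G'G``; ``eig_Q``/``eig_lambda`` eigendecompose the
    *inverse* Gram matrix, ``(G'G)^{-1} = Q diag(eig_lambda) Q'``.
    """

    gamma_hat: np.ndarray
    Gamma_hat: np.ndarray
    gram: np.ndarray
    eig_Q: np.ndarray
    eig_lambda: np.ndarray

    @property
    def m(self) -> int:
        return self.gamma_hat.shape[0]

    def gram_inverse(self) -> np.ndarray:
        return (self.eig_Q * self.eig_lambda) @ self.eig_Q.T


@dataclass
class MarginalCoefs:
    """Per-variant simple-regression slopes and the outcome-slope SEs."""

    gamma_tilde: np.ndarray
    Gamma_tilde: np.ndarray
    se_Gamma_tilde: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gamma_tilde", "Gamma_tilde", "se_Gamma_tilde"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if not (self.gamma_tilde.shape == self.Gamma_tilde.shape == self.se_Gamma_tilde.shape):
            raise ValueError("marginal coefficient vectors must share a length")
        if np.any(self.se_Gamma_tilde <= 0):
            raise ValueError("all outcome-slope standard errors must be positive")

    @property
    def m(self) -> int:
        return self.gamma_tilde.shape[0]


@dataclass
class VarianceComponents:
    """Mean/variance of the pleiotropic effect and the outcome error variance.

    ``r2`` is the variance ratio sigma_alpha^2 / sigma_y^2 that indexes the
    profile likelihood.
    """

    mu_alpha: float
    sigma_alpha2: float
    sigma_y2: float

    def __post_init__(self) -> None:
        if self.sigma_y2 <= 0:
            raise ValueError("sigma_y2 must be positive")
        if self.sigma_alpha2 < 0:
            raise ValueError("sigma_alpha2 must be nonnegative")

    @property
    def r2(self) -> float:
        return self.sigma_alpha2 / self.sigma_y2


def center_columns(matrix: np.ndarray) -> np.ndarray:
    """Subtract the column mean from every column."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        return matrix - matrix.mean()
    if matrix.shape[0] < 1:
        raise ValueError("need at least one row to center")
    return matrix - matrix.mean(axis=0, keepdims=True)


def _signed_eigh(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition with a deterministic sign convention.

    Eigenvalues come back in *ascending* order from LAPACK; each eigenvector
    is flipped so its first entry of non-negligible magnitude is positive.
    """
    evals, evecs = np.linalg.eigh(mat)
    scale = np.abs(evecs).max(axis=0)
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        idx = np.flatnonzero(np.abs(col) > 1e-12 * max(scale[k], 1.0))
        if idx.size and col[idx[0]] < 0:
            evecs[:, k] = -col
    return evals, evecs


def joint_coefs(G: GenotypeMatrix, P: PhenotypePair) -> JointCoefs:
    """Multiple-regression coefficients of exposure and outcome on all variants.

    Computes ``gamma_hat = (G'G)^{-1} G'X`` and ``Gamma_hat = (G'G)^{-1} G'Y``
    on the centered data, and caches the eigendecomposition of the inverse
    Gram matrix for downstream likelihood work.

    Raises
    ------
    RankDeficiencyError
        If the Gram matrix has condition number above ``COND_MAX``; the
        message names the columns most involved in the near-null space so the
        user can prune them.
    """
    G = G.center()
    P = P.center()
    if P.n != G.n:
        raise ValueError("phenotype length does not match genotype sample count")
    if G.n <= G.m:
        raise ValueError(f"need n > m for the Gram inversion (n={G.n}, m={G.m})")
    S = G.values.T @ G.values
    evals, Q = _signed_eigh(S)
    if evals[0] <= 0 or evals[-1] / max(evals[0], np.finfo(float).tiny) > COND_MAX:
        null_vec = Q[:, 0]
        worst = np.argsort(-np.abs(null_vec))[:3]
        names = [G.variant_ids[j] for j in worst]
        raise RankDeficiencyError(
            "genotype Gram matrix is singular or ill-conditioned "
            f"(condition number > {COND_MAX:.0e}); most collinear columns: {names}"
        )
    # eigenvalues of S^{-1} are 1/eigenvalues of S; descending order
    lam = 1.0 / evals
    order = np.argsort(-lam, kind="stable")
    lam = lam[order]
    Q = Q[:, order]
    GtX = G.values.T @ P.exposure
    GtY = G.values.T @ P.outcome
    Sinv = (Q * lam) @ Q.T
    return JointCoefs(
        gamma_hat=Sinv @ GtX,
        Gamma_hat=Sinv @ GtY,
        gram=S,
        eig_Q=Q,
        eig_lambda=lam,
    )


def marginal_coefs(G: GenotypeMatrix, P: PhenotypePair) -> MarginalCoefs:
    """Per-variant simple-regression slopes of exposure and outcome.

    On centered data the no-intercept slope is ``G_j'y / G_j'G_j``; the SE of
    the outcome slope uses the residual sum of squares with ``n - 1``
    denominator degrees of freedom (one slope, no intercept).
    """
    G = G.center()
    P = P.center()
    if P.n != G.n:
        raise ValueError("phenotype length does not match genotype sample count")
    V = G.values
    ss = np.einsum("ij,ij->j", V, V)
    if np.any(ss == 0):
        raise ValueError("zero-variance genotype column in marginal regression")
    gamma_tilde = (V.T @ P.exposure) / ss
    Gamma_tilde = (V.T @ P.outcome) / ss
    yty = float(P.outcome @ P.outcome)
    rss = yty - Gamma_tilde**2 * ss
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / (G.n - 1) / ss)
    se = np.maximum(se, np.finfo(float).tiny)
    return MarginalCoefs(gamma_tilde, Gamma_tilde, se)


def weight_matrix(vc: VarianceComponents, jc: JointCoefs) -> np.ndarray:
    """Precision matrix W = [sigma_alpha^2 I + sigma_y^2 (G'G)^{-1}]^{-1}.

    Built in the eigenbasis as ``sigma_y^{-2} Q diag(1/(r2 + lam)) Q'``,
    which agrees with the dense inversion (see :func:`weight_matrix_dense`)
    but costs one diagonal scaling instead of a solve.
    """
    d = 1.0 / (vc.sigma_y2 * (vc.r2 + jc.eig_lambda))
    return (jc.eig_Q * d) @ jc.eig_Q.T


def weight_matrix_dense(vc: VarianceComponents, jc: JointCoefs) -> np.ndarray:
    """W by direct dense inversion; the cross-check form of :func:`weight_matrix`."""
    m = jc.m
    return np.linalg.inv(vc.sigma_alpha2 * np.eye(m) + vc.sigma_y2 * jc.gram_inverse())
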