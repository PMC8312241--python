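"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own linear-algebra paths:
dense matrix inversion for the likelihood, augmented normal equations for
every weighted regression, and an explicit projection matrix for the
W^{1/2}1 projector.
"""

import numpy as np
import pytest

from pldmr import ScenarioConfig, simulate_dataset
from pldmr.model_core import joint_coefs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset():
    """A modest simulated cohort (n=400, m=8) with LD and pleiotropy."""
    cfg = ScenarioConfig(
        n=400, m=8, rho_g=0.4, mu_alpha=0.1, sigma_alpha=0.1, beta=0.05, seed=11,
    )
    ds = simulate_dataset(cfg, np.random.default_rng(11))
    return cfg, ds


@pytest.fixture
def small_joint(small_dataset):
    cfg, ds = small_dataset
    return joint_coefs(ds.genotypes.center(), ds.phenotypes.center())


def dense_nll(mu_alpha, beta, sigma_alpha2, sigma_y2, jc):
    """Untransformed mixed-effects NLL via dense W, the likelihood oracle."""
    m = jc.m
    S_inv = np.linalg.inv(jc.gram)
    W = np.linalg.inv(sigma_alpha2 * np.eye(m) + sigma_y2 * S_inv)
    resid = jc.Gamma_hat - mu_alpha * np.ones(m) - beta * jc.gamma_hat
    sign, logdet = np.linalg.slogdet(W)
    assert sign > 0
    return 0.5 * m * np.log(2 * np.pi) - 0.5 * logdet + 0.5 * resid @ W @ resid


def gls_line_oracle(y, x, W):
    """Weighted LS of y on [1, x] with full weight matrix W, by augmented
    normal equations; returns (intercept, slope, se_slope)."""
    X = np.column_stack([np.ones_like(x), x])
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ W @ y)
    cov = np.linalg.inv(XtWX)
    return coef[0], coef[1], np.sqrt(cov[1, 1])


def projector_W_half_ones(W):
    """Explicit orthogonal projection onto W^{1/2} 1."""
    evals, evecs = np.linalg.eigh(W)
    W_half = (evecs * np.sqrt(evals)) @ evecs.T
    v = W_half @ np.ones(W.shape[0])
    return np.outer(v, v) / (v @ v)
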