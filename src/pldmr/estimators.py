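"""Causal-effect estimators for individual-level Mendelian randomization.

The centrepiece is PLDMR: a mixed-effects model for the multiple-regression
coefficients that jointly accounts for directional pleiotropy (through the
mean and variance of the random pleiotropic effect) and linkage
disequilibrium among the instruments (through the genotype Gram matrix).
Writing ``Gamma_hat`` and ``gamma_hat`` for the multiple-regression
coefficients of outcome and exposure on the m variants,

    Gamma_hat = mu_alpha * 1 + beta * gamma_hat + e,   e ~ N(0, W^{-1}),
    W = [sigma_alpha^2 I + sigma_y^2 (G'G)^{-1}]^{-1},

so that the causal effect ``beta`` is the slope of a generalized least
squares line with intercept ``mu_alpha``.  With the eigendecomposition
``(G'G)^{-1} = Q diag(lam) Q'`` and the variance ratio
``r2 = sigma_alpha^2 / sigma_y2``, the likelihood diagonalizes; the full
MLE reduces to a one-dimensional profile over r2.

Estimator family
----------------
``fit_pldmr``     REML fit of r2 via a 1-D profile; Kenward-Roger-adjusted
                  plug-in variance, t(m-2).
``fit_pldmr_t``   weighted LS at the *true* variance components (oracle).
``fit_pldmr_a``   large-n approximation: OLS of Gamma_hat on gamma_hat.
``fit_ldmr``      sigma_alpha^2 = 0 special case, closed form.
``fit_mr_egger``  summary-statistic Egger regression (marginal coefficients).
``fit_ivw``       inverse-variance weighted estimate (no intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .model_core import (
    GenotypeMatrix,
    JointCoefs,
    MarginalCoefs,
    PhenotypePair,
    VarianceComponents,
    joint_coefs,
)

__all__ = [
    "MRFit",
    "t_inference",
    "pldmr_nll",
    "restricted_nll",
    "profile_given_r2",
    "fit_pldmr",
    "fit_pldmr_t",
    "fit_pldmr_a",
    "fit_ldmr",
    "fit_mr_egger",
    "fit_ivw",
]

#: Upper bound of the initial r2 search window; expanded if the optimum
#: presses against it.
R2_MAX = 1e4

#: Floor for the profiled outcome-error variance; hitting it means the data
#: fit the line exactly (a boundary case reported via ``converged``).
SIGMA_Y2_FLOOR = 1e-30


@dataclass
class MRFit:
    """One estimator's output: point estimate, inference, and diagnostics."""

    method: str
    beta_hat: float
    se_beta: float
    df: int
    t_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    mu_alpha_hat: Optional[float] = None
    r2_hat: Optional[float] = None
    sigma_y2_hat: Optional[float] = None
    overdispersion: Optional[float] = None
    converged: bool = True
    nll_at_optimum: Optional[float] = None

    def to_record(self) -> dict:
        """Flat key/value record with deterministic field order."""
        return asdict(self)


def t_inference(
    beta_hat: float,
    se: float,
    df: int,
    beta0: float = 0.0,
    level: float = 0.95,
) -> tuple[float, float, float, float]:
    """Two-sided t test of H0: beta = beta0 and an equal-tailed CI.

    Returns ``(t_stat, p_value, ci_low, ci_high)`` using the t distribution
    with ``df`` degrees of freedom.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if se <= 0:
        raise ValueError("standard error must be positive")
    t_stat = (beta_hat - beta0) / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    half = stats.t.ppf(0.5 + level / 2.0, df) * se
    return t_stat, p, beta_hat - half, beta_hat + half


# ---------------------------------------------------------------------------
# PLDMR likelihood and profile
# ---------------------------------------------------------------------------

def pldmr_nll(
    mu_alpha: float,
    beta: float,
    r2: float,
    sigma_y2: float,
    jc: JointCoefs,
) -> float:
    """Negative log-likelihood of the PLDMR model, eigenbasis form.

    With ``u = Q'(Gamma_hat - mu_alpha 1 - beta gamma_hat)``:

        NLL = (m/2) log(2 pi sigma_y2) + (1/2) sum_k log(r2 + lam_k)
              + (1 / (2 sigma_y2)) sum_k u_k^2 / (r2 + lam_k)
    """
    for name, v in (("mu_alpha", mu_alpha), ("beta", beta), ("r2", r2), ("sigma_y2", sigma_y2)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite parameter {name}={v}")
    if r2 < 0:
        raise ValueError("r2 must be nonnegative")
    if sigma_y2 <= 0:
        raise ValueError("sigma_y2 must be positive")
    resid = jc.Gamma_hat - mu_alpha - beta * jc.gamma_hat
    u = jc.eig_Q.T @ resid
    d = r2 + jc.eig_lambda
    m = jc.m
    return float(
        0.5 * m * np.log(2.0 * np.pi * sigma_y2)
        + 0.5 * np.sum(np.log(d))
        + 0.5 * np.sum(u * u / d) / sigma_y2
    )


def _weighted_line(a: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Weighted LS of ``a`` on ``[1, x]`` with diagonal precision ``w``.

    Returns ``(intercept, slope, sw, det)`` where ``sw = sum(w)`` and
    ``det = sum(w) sum(w x^2) - (sum(w x))^2``; the GLS slope variance is
    ``sw / det`` (in the units of the precision weights).
    """
    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swxx = float(np.sum(w * x * x))
    swa = float(np.sum(w * a))
    swxa = float(np.sum(w * x * a))
    det = sw * swxx - swx * swx
    if det <= 0 or det <= 1e-14 * sw * swxx:
        raise ValueError("regressor is collinear with the intercept (constant gamma)")
    slope = (sw * swxa - swx * swa) / det
    intercept = (swa - swx * slope) / sw
    return intercept, slope, sw, det


def profile_given_r2(r2: float, jc: JointCoefs) -> tuple[float, float, float, float]:
    """Closed-form profile of (mu_alpha, beta, sigma_y2) at a fixed r2.

    For fixed r2 the model is a two-parameter generalized least squares of
    ``Q'Gamma_hat`` on ``[Q'1, Q'gamma_hat]`` with diagonal weights
    ``1/(r2 + lam_k)``; the outcome-error variance is then the weighted mean
    squared residual.  Returns ``(mu_alpha, beta, sigma_y2, nll)`` with
    ``nll`` equal to :func:`pldmr_nll` at the returned quadruple.
    """
    if r2 < 0:
        raise ValueError("r2 must be nonnegative")
    Q = jc.eig_Q
    a = Q.T @ jc.Gamma_hat
    ones_t = Q.T @ np.ones(jc.m)
    g = Q.T @ jc.gamma_hat
    w = 1.0 / (r2 + jc.eig_lambda)
    # GLS of a on [ones_t, g]: reduce to the centered-slope form in the
    # metric of w, which stays valid because ones_t is not the constant
    # vector in the eigenbasis.
    sw = float(np.sum(w * ones_t * ones_t))
    swx = float(np.sum(w * ones_t * g))
    swxx = float(np.sum(w * g * g))
    swa = float(np.sum(w * ones_t * a))
    swxa = float(np.sum(w * g * a))
    det = sw * swxx - swx * swx
    if det <= 0 or det <= 1e-14 * sw * swxx:
        raise ValueError("gamma_hat is collinear with the all-ones vector")
    beta = (sw * swxa - swx * swa) / det
    mu_alpha = (swa - swx * beta) / sw
    u = a - mu_alpha * ones_t - beta * g
    sigma_y2 = float(np.sum(w * u * u) / jc.m)
    sigma_y2 = max(sigma_y2, SIGMA_Y2_FLOOR)
    nll = pldmr_nll(mu_alpha, beta, r2, sigma_y2, jc)
    return mu_alpha, beta, sigma_y2, nll


def restricted_nll(
    mu_alpha: float,
    beta: float,
    r2: float,
    sigma_y2: float,
    jc: JointCoefs,
) -> float:
    """Restricted (REML) negative log-likelihood of the PLDMR model.

    The plain NLL plus the REML adjustment ``(1/2) log det(X' V^{-1} X)``
    with design ``X = [1, gamma_hat]`` and ``V = sigma_y2 (r2 I + Lam)``.
    Joint minimization over all four parameters yields the GLS line at the
    REML variance components, with ``sigma_y2 = weighted RSS / (m - 2)``
    rather than the ML ``/ m`` — the usual degrees-of-freedom correction
    for the two estimated line parameters.
    """
    base = pldmr_nll(mu_alpha, beta, r2, sigma_y2, jc)
    v = sigma_y2 * (r2 + jc.eig_lambda)
    ones_t = jc.eig_Q.T @ np.ones(jc.m)
    g = jc.eig_Q.T @ jc.gamma_hat
    sw = np.sum(ones_t * ones_t / v)
    swx = np.sum(ones_t * g / v)
    swxx = np.sum(g * g / v)
    det = sw * swxx - swx * swx
    if det <= 0:
        raise ValueError("gamma_hat is collinear with the all-ones vector")
    return float(base + 0.5 * np.log(det))


def _profile_reml(r2: float, jc: JointCoefs) -> tuple[float, float, float, float]:
    """Profile of the restricted likelihood at fixed r2.

    The line is the same GLS solution as :func:`profile_given_r2`; the
    variance estimate divides the weighted RSS by ``m - 2``.  Returns
    ``(mu_alpha, beta, sigma_y2, restricted_nll)``.
    """
    mu_alpha, beta, sigma_y2_ml, _ = profile_given_r2(r2, jc)
    sigma_y2 = max(sigma_y2_ml * jc.m / (jc.m - 2), SIGMA_Y2_FLOOR)
    crit = restricted_nll(mu_alpha, beta, r2, sigma_y2, jc)
    return mu_alpha, beta, sigma_y2, crit


def _kr_adjusted_beta_var(jc: JointCoefs, r2: float, sigma_y2: float) -> float:
    """Small-sample adjusted variance of the GLS slope (Kenward-Roger form).

    The naive plug-in variance Phi = (X'V^{-1}X)^{-1} treats the variance
    components as known; with only m coefficient-level observations their
    estimation error is material and the Wald test is anti-conservative.
    This applies the standard first-order inflation
    ``Phi_A = Phi + 2 Phi [sum_ij W_ij (Q_ij - P_i Phi P_j)] Phi`` for a
    covariance linear in the components (sigma_alpha2, sigma_y2), with W
    the inverse REML information.  Returns the (2,2) slope entry of Phi_A.
    """
    m = jc.m
    lam = jc.eig_lambda
    o = jc.eig_Q.T @ np.ones(m)
    g = jc.eig_Q.T @ jc.gamma_hat
    sa2 = r2 * sigma_y2
    v = sa2 + sigma_y2 * lam  # diagonal of V in the eigenbasis
    X = np.column_stack([o, g])

    def quad(w):
        return np.array([
            [np.sum(w * o * o), np.sum(w * o * g)],
            [np.sum(w * o * g), np.sum(w * g * g)],
        ])

    Phi = np.linalg.inv(quad(1.0 / v))
    # dV/d sigma_alpha2 = I, dV/d sigma_y2 = diag(lam)
    P = [quad(1.0 / v**2), quad(lam / v**2)]
    Qm = [[quad(1.0 / v**3), quad(lam / v**3)],
          [quad(lam / v**3), quad(lam * lam / v**3)]]
    vinv = 1.0 / v
    Pmat = np.diag(vinv) - (vinv[:, None] * X) @ Phi @ (X.T * vinv[None, :])
    D = [np.ones(m), lam]
    info = np.zeros((2, 2))
    for i in range(2):
        PDi = Pmat * D[i][None, :]
        for j in range(i, 2):
            PDj = Pmat * D[j][None, :]
            info[i, j] = info[j, i] = 0.5 * np.sum(PDi * PDj.T)
    try:
        Wc = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(Phi[1, 1])  # singular information: fall back to plug-in
    if r2 == 0.0:
        # boundary estimate sigma_alpha2 = 0: the one-sided constraint makes
        # the sampling distribution of the constrained component a
        # point-mass/half-normal mixture whose variance is half the
        # unconstrained one (boundary asymptotics); shrink its contribution
        # accordingly so the adjustment is not overstated
        S = np.diag([np.sqrt(0.5), 1.0])
        Wc = S @ Wc @ S
    corr = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            corr += Wc[i, j] * (Qm[i][j] - P[i] @ Phi @ P[j])
    Phi_A = Phi + 2.0 * Phi @ corr @ Phi
    # the adjustment is additive and can only sensibly inflate; guard the
    # degenerate case where numerical noise would deflate it
    return float(max(Phi_A[1, 1], Phi[1, 1]))


def fit_pldmr(
    G: GenotypeMatrix,
    P: PhenotypePair,
    beta0: float = 0.0,
    level: float = 0.95,
    jc: Optional[JointCoefs] = None,
) -> MRFit:
    """Full PLDMR maximum-likelihood fit with plug-in variance.

    Estimates the variance ratio r2 by restricted maximum likelihood —
    bounded one-dimensional minimization of the profiled restricted NLL over
    r2 (the line parameters and sigma_y2 have closed forms at each r2; see
    :func:`restricted_nll`).  r2 = 0 is a legitimate boundary estimate (the
    fit then coincides with LDMR's point estimate).  The slope variance is
    the plug-in GLS form

        Var(beta_hat) = [gamma' W gamma - (1'W gamma)^2 / (1'W 1)]^{-1}

    with W at the estimated components, inflated by the Kenward-Roger-type
    small-sample adjustment for their estimation error
    (:func:`_kr_adjusted_beta_var`); inference uses t(m - 2).
    """
    if jc is None:
        jc = joint_coefs(G, P)
    m = jc.m
    if m < 3:
        raise ValueError(f"PLDMR needs at least 3 instruments (m={m}, df would be {m - 2})")

    def objective(r2: float) -> float:
        return _profile_reml(r2, jc)[3]

    r2_hi = R2_MAX
    converged = True
    while True:
        res = optimize.minimize_scalar(
            objective, bounds=(0.0, r2_hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.x < 0.95 * r2_hi or r2_hi >= 1e12:
            break
        r2_hi *= 100.0  # optimum presses the window; widen it
    converged = bool(res.success) if hasattr(res, "success") else True
    # the bounded minimizer cannot land exactly on the boundary; check it
    nll0 = objective(0.0)
    if nll0 <= res.fun:
        r2_hat, nll = 0.0, nll0
    else:
        r2_hat, nll = float(res.x), float(res.fun)
    mu_alpha, beta_hat, sigma_y2, nll = _profile_reml(r2_hat, jc)
    if sigma_y2 <= SIGMA_Y2_FLOOR * m / (m - 2):
        converged = False  # exact-fit boundary: variance estimate degenerate
    se = float(np.sqrt(_kr_adjusted_beta_var(jc, r2_hat, sigma_y2)))
    t_stat, p, lo, hi = t_inference(beta_hat, se, m - 2, beta0, level)
    return MRFit(
        method="PLDMR",
        beta_hat=float(beta_hat),
        se_beta=se,
        df=m - 2,
        t_stat=t_stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        mu_alpha_hat=float(mu_alpha),
        r2_hat=float(r2_hat),
        sigma_y2_hat=float(sigma_y2),
        converged=converged,
        nll_at_optimum=float(nll),
    )


def fit_pldmr_t(
    G: GenotypeMatrix,
    P: PhenotypePair,
    vc_true: VarianceComponents,
    beta0: float = 0.0,
    level: float = 0.95,
    jc: Optional[JointCoefs] = None,
) -> MRFit:
    """PLDMR weighted least squares at the *true* variance components.

    The oracle variant used in simulation studies: W is built from the known
    sigma_alpha^2 and sigma_y^2 rather than their MLEs, so only the line
    (mu_alpha, beta) is estimated.
    """
    if jc is None:
        jc = joint_coefs(G, P)
    m = jc.m
    if m < 3:
        raise ValueError(f"needs at least 3 instruments (m={m})")
    Q = jc.eig_Q
    a = Q.T @ jc.Gamma_hat
    ones_t = Q.T @ np.ones(m)
    g = Q.T @ jc.gamma_hat
    w = 1.0 / (vc_true.sigma_y2 * (vc_true.r2 + jc.eig_lambda))
    sw = float(np.sum(w * ones_t * ones_t))
    swx = float(np.sum(w * ones_t * g))
    swxx = float(np.sum(w * g * g))
    swa = float(np.sum(w * ones_t * a))
    swxa = float(np.sum(w * g * a))
    det = sw * swxx - swx * swx
    if det <= 0 or det <= 1e-14 * sw * swxx:
        raise ValueError("gamma_hat is collinear with the all-ones vector")
    beta_hat = (sw * swxa - swx * swa) / det
    mu_alpha = (swa - swx * beta_hat) / sw
    se = float(np.sqrt(sw / det))
    t_stat, p, lo, hi = t_inference(beta_hat, se, m - 2, beta0, level)
    return MRFit(
        method="PLDMR_t",
        beta_hat=float(beta_hat),
        se_beta=se,
        df=m - 2,
        t_stat=t_stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        mu_alpha_hat=float(mu_alpha),
        r2_hat=float(vc_true.r2),
        sigma_y2_hat=float(vc_true.sigma_y2),
    )


def fit_ldmr(
    G: GenotypeMatrix,
    P: PhenotypePair,
    beta0: float = 0.0,
    level: float = 0.95,
    jc: Optional[JointCoefs] = None,
) -> MRFit:
    """LDMR: the sigma_alpha^2 = 0 special case, in closed form.

    The point estimate is the Gram-weighted regression of Gamma_hat on
    gamma_hat with intercept,

        beta_hat = gamma' A Gamma / gamma' A gamma,
        A = S - S J S / (1'S1),   S = G'G,  J = all-ones,

    and the slope variance is ``sigma_y2_hat / (gamma' A gamma)`` with
    sigma_y2_hat the S-weighted residual sum of squares over (m - 2).
    """
    if jc is None:
        jc = joint_coefs(G, P)
    m = jc.m
    if m < 3:
        raise ValueError(f"needs at least 3 instruments (m={m})")
    S = jc.gram
    ones = np.ones(m)
    S1 = S @ ones
    s11 = float(ones @ S1)
    if s11 <= 0:
        raise ValueError("1'G'G1 must be positive for an SPD Gram matrix")
    A = S - np.outer(S1, S1) / s11
    gAg = float(jc.gamma_hat @ A @ jc.gamma_hat)
    if gAg <= 0:
        raise ValueError("gamma_hat is collinear with the all-ones vector")
    beta_hat = float(jc.gamma_hat @ A @ jc.Gamma_hat) / gAg
    resid0 = jc.Gamma_hat - beta_hat * jc.gamma_hat
    mu_alpha = float(S1 @ resid0) / s11
    resid = resid0 - mu_alpha
    sigma_y2 = float(resid @ S @ resid) / (m - 2)
    sigma_y2 = max(sigma_y2, SIGMA_Y2_FLOOR)
    se = float(np.sqrt(sigma_y2 / gAg))
    t_stat, p, lo, hi = t_inference(beta_hat, se, m - 2, beta0, level)
    return MRFit(
        method="LDMR",
        beta_hat=beta_hat,
        se_beta=se,
        df=m - 2,
        t_stat=t_stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        mu_alpha_hat=mu_alpha,
        r2_hat=0.0,
        sigma_y2_hat=float(sigma_y2),
    )


def fit_pldmr_a(
    jc: JointCoefs,
    beta0: float = 0.0,
    level: float = 0.95,
) -> MRFit:
    """Large-n approximation: ordinary least squares of Gamma_hat on gamma_hat.

    When n is large, G'G = O(n) makes W approximately proportional to the
    identity, so the weighted fit collapses to a simple regression with
    intercept; the residual mean square with m - 2 df gives the slope SE.
    """
    m = jc.m
    if m < 3:
        raise ValueError(f"needs at least 3 instruments (m={m})")
    w = np.ones(m)
    mu_alpha, beta_hat, sw, det = _weighted_line(jc.Gamma_hat, jc.gamma_hat, w)
    resid = jc.Gamma_hat - mu_alpha - beta_hat * jc.gamma_hat
    s2 = float(resid @ resid) / (m - 2)
    s2 = max(s2, SIGMA_Y2_FLOOR)
    se = float(np.sqrt(s2 * sw / det))
    t_stat, p, lo, hi = t_inference(beta_hat, se, m - 2, beta0, level)
    return MRFit(
        method="PLDMR_a",
        beta_hat=float(beta_hat),
        se_beta=se,
        df=m - 2,
        t_stat=t_stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        mu_alpha_hat=float(mu_alpha),
    )


def fit_mr_egger(
    mc: MarginalCoefs,
    beta0: float = 0.0,
    level: float = 0.95,
) -> MRFit:
    """MR-Egger regression on the marginal (per-variant) coefficients.

    Weighted least squares of Gamma_tilde on gamma_tilde with intercept and
    weights SE(Gamma_tilde)^{-2}; a multiplicative overdispersion parameter
    is estimated from the weighted residual mean square and floored at 1
    (no under-dispersion).  Inference on the slope uses t(m - 2).
    """
    m = mc.m
    if m < 3:
        raise ValueError(f"needs at least 3 instruments (m={m})")
    w = 1.0 / mc.se_Gamma_tilde**2
    intercept, slope, sw, det = _weighted_line(mc.Gamma_tilde, mc.gamma_tilde, w)
    resid = mc.Gamma_tilde - intercept - slope * mc.gamma_tilde
    overdisp = max(1.0, float(np.sum(w * resid * resid)) / (m - 2))
    se = float(np.sqrt(overdisp * sw / det))
    t_stat, p, lo, hi = t_inference(slope, se, m - 2, beta0, level)
    return MRFit(
        method="MR-Egger",
        beta_hat=float(slope),
        se_beta=se,
        df=m - 2,
        t_stat=t_stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        mu_alpha_hat=float(intercept),
        overdispersion=overdisp,
    )


def fit_ivw(
    mc: MarginalCoefs,
    beta0: float = 0.0,
    level: float = 0.95,
) -> MRFit:
    """Inverse-variance weighted estimate: Egger with the intercept pinned at 0.

    No-intercept weighted regression of Gamma_tilde on gamma_tilde with
    weights SE(Gamma_tilde)^{-2}; fixed-effect standard error and t(m - 1)
    inference.
    """
    m = mc.m
    w = 1.0 / mc.se_Gamma_tilde**2
    sxx = float(np.sum(w * mc.gamma_tilde**2))
    if sxx <= 0:
        raise ValueError("all-zero gamma_tilde: no instrument strength")
    beta_hat = float(np.sum(w * mc.gamma_tilde * mc.Gamma_tilde)) / sxx
    se = float(np.sqrt(1.0 / sxx))
    if m >= 2:
        t_stat, p, lo, hi = t_inference(beta_hat, se, m - 1, beta0, level)
    else:  # single-instrument Wald ratio: point estimate only
        t_stat, p, lo, hi = np.nan, np.nan, np.nan, np.nan
    return MRFit(
        method="IVW",
        beta_hat=beta_hat,
        se_beta=se,
        df=max(m - 1, 0),
        t_stat=t_stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
    )
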