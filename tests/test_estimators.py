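"""Oracle and property tests for the estimator family.

Every weighted-least-squares path is checked against an independent
augmented-normal-equations solve; the profile-likelihood optimizer is
checked against a multi-start full-dimensional optimizer; the eigenbasis
likelihood is checked against a dense-matrix evaluation.
"""

import numpy as np
import pytest
from scipy import optimize, stats

from pldmr.model_core import (
    GenotypeMatrix,
    JointCoefs,
    MarginalCoefs,
    PhenotypePair,
    VarianceComponents,
    joint_coefs,
    marginal_coefs,
    weight_matrix,
)
from pldmr.estimators import (
    fit_ivw,
    fit_ldmr,
    fit_mr_egger,
    fit_pldmr,
    fit_pldmr_a,
    fit_pldmr_t,
    pldmr_nll,
    profile_given_r2,
    restricted_nll,
    t_inference,
)
from pldmr.simulate import ScenarioConfig, simulate_dataset
from conftest import dense_nll, gls_line_oracle


def _sim_joint(seed, n=300, m=8, **kw):
    cfg = ScenarioConfig(n=n, m=m, rho_g=kw.pop("rho_g", 0.4),
                         mu_alpha=kw.pop("mu_alpha", 0.1),
                         sigma_alpha=kw.pop("sigma_alpha", 0.1),
                         beta=kw.pop("beta", 0.05), seed=seed, **kw)
    ds = simulate_dataset(cfg, np.random.default_rng(seed))
    G, P = ds.genotypes.center(), ds.phenotypes.center()
    return cfg, G, P, joint_coefs(G, P)


class TestLikelihood:
    def test_zero_residual_closed_form(self, small_joint):
        jc = small_joint
        mu, beta = 0.3, 0.05
        jc_exact = JointCoefs(
            gamma_hat=jc.gamma_hat,
            Gamma_hat=mu + beta * jc.gamma_hat,
            gram=jc.gram, eig_Q=jc.eig_Q, eig_lambda=jc.eig_lambda,
        )
        sy2 = 2.5
        expected = 0.5 * jc.m * np.log(2 * np.pi * sy2) + 0.5 * np.sum(np.log(jc.eig_lambda))
        assert pldmr_nll(mu, beta, 0.0, sy2, jc_exact) == pytest.approx(expected, rel=1e-12)

    def test_scalar_unit_case_is_zero(self):
        jc = JointCoefs(
            gamma_hat=np.array([1.0]), Gamma_hat=np.array([1.0]),
            gram=np.array([[1.0]]), eig_Q=np.array([[1.0]]),
            eig_lambda=np.array([1.0]),
        )
        # u = Gamma - mu - beta*gamma = 1 - 0 - 1 = 0; sigma_y2 = 1/(2 pi)
        assert pldmr_nll(0.0, 1.0, 0.0, 1.0 / (2 * np.pi), jc) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_eigenbasis_matches_dense_oracle(self, seed, small_joint):
        jc = small_joint
        prng = np.random.default_rng(seed)
        mu, beta = prng.normal(), prng.normal()
        r2 = float(prng.uniform(0.0, 0.5))
        sy2 = float(prng.uniform(0.5, 5.0))
        transformed = pldmr_nll(mu, beta, r2, sy2, jc)
        dense = dense_nll(mu, beta, r2 * sy2, sy2, jc)
        assert transformed == pytest.approx(dense, rel=1e-8)

    def test_nonfinite_inputs_rejected(self, small_joint):
        with pytest.raises(ValueError):
            pldmr_nll(np.nan, 0.0, 0.1, 1.0, small_joint)
        with pytest.raises(ValueError):
            pldmr_nll(0.0, 0.0, -0.1, 1.0, small_joint)


class TestProfile:
    def test_grid_oracle_at_fixed_r2(self, small_joint):
        jc = small_joint
        r2 = 0.02
        mu, beta, sy2, nll = profile_given_r2(r2, jc)
        assert nll == pytest.approx(pldmr_nll(mu, beta, r2, sy2, jc), rel=1e-12)
        mus = np.linspace(mu - 0.5, mu + 0.5, 100)
        betas = np.linspace(beta - 0.5, beta + 0.5, 100)
        w = 1.0 / (r2 + jc.eig_lambda)
        ones_t = jc.eig_Q.T @ np.ones(jc.m)
        g = jc.eig_Q.T @ jc.gamma_hat
        a = jc.eig_Q.T @ jc.Gamma_hat
        best = np.inf
        for mu_i in mus:
            u = a - mu_i * ones_t - np.outer(betas, g)
            sy2_grid = np.sum(w * u * u, axis=1) / jc.m
            vals = (0.5 * jc.m * np.log(2 * np.pi * sy2_grid)
                    + 0.5 * np.sum(np.log(r2 + jc.eig_lambda)) + 0.5 * jc.m)
            best = min(best, vals.min())
        assert nll <= best + 1e-10

    def test_large_r2_limit_recovers_ols(self, small_joint):
        jc = small_joint
        mu, beta, _, _ = profile_given_r2(1e12, jc)
        X = np.column_stack([np.ones(jc.m), jc.gamma_hat])
        coef, *_ = np.linalg.lstsq(X, jc.Gamma_hat, rcond=None)
        assert mu == pytest.approx(coef[0], abs=1e-5)
        assert beta == pytest.approx(coef[1], abs=1e-5)

    def test_collinear_design_rejected(self):
        jc = JointCoefs(
            gamma_hat=np.full(4, 2.0), Gamma_hat=np.arange(4.0),
            gram=np.eye(4), eig_Q=np.eye(4), eig_lambda=np.ones(4),
        )
        with pytest.raises(ValueError, match="collinear"):
            profile_given_r2(0.1, jc)


class TestFitPLDMR:
    def test_noiseless_recovery(self, rng):
        # alpha identically mu_alpha, no outcome noise: exact linear relation
        n, m, beta, mu_alpha = 200, 6, 0.05, 0.1
        G = GenotypeMatrix(rng.integers(0, 3, size=(n, m)).astype(float))
        Gc = G.center().values
        gamma = rng.uniform(0.5, 4, size=m)
        x = Gc @ gamma + rng.normal(size=n)
        y = Gc @ (mu_alpha * np.ones(m)) + x * beta
        fit = fit_pldmr(G, PhenotypePair(x, y))
        assert fit.beta_hat == pytest.approx(beta, abs=1e-8)
        assert fit.mu_alpha_hat == pytest.approx(mu_alpha, abs=1e-8)
        assert fit.r2_hat == 0.0

    def test_optimizer_dominates_truth(self):
        cfg, G, P, jc = _sim_joint(5)
        fit = fit_pldmr(G, P, jc=jc)
        true_r2 = cfg.sigma_alpha**2 / cfg.sigma_y**2
        crit_true = restricted_nll(cfg.mu_alpha, cfg.beta, true_r2, cfg.sigma_y**2, jc)
        assert fit.nll_at_optimum <= crit_true + 1e-10

    def test_too_few_instruments(self, rng):
        G = GenotypeMatrix(rng.integers(0, 3, size=(20, 2)).astype(float))
        with pytest.raises(ValueError, match="at least 3"):
            fit_pldmr(G, PhenotypePair(rng.normal(size=20), rng.normal(size=20)))

    @pytest.mark.parametrize("seed", range(20))
    def test_profile_matches_multistart_full_optimizer(self, seed):
        """1-D r2 profile and 4-parameter multi-start optimization agree."""
        _, G, P, jc = _sim_joint(seed + 100)
        fit = fit_pldmr(G, P, jc=jc)

        def nll4(theta):
            mu, beta, log_r2, log_sy2 = theta
            return restricted_nll(mu, beta, np.exp(log_r2), np.exp(log_sy2), jc)

        best = None
        starts = [
            (0.0, 0.0, np.log(0.01), 0.0),
            (fit.mu_alpha_hat + 0.3, fit.beta_hat - 0.2, np.log(0.1), np.log(2.0)),
            (0.1, 0.05, np.log(1.0), np.log(4.0)),
            (-0.2, 0.2, np.log(1e-4), np.log(0.5)),
        ]
        for x0 in starts:
            res = optimize.minimize(nll4, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        assert fit.nll_at_optimum <= best.fun + 1e-7
        assert fit.beta_hat == pytest.approx(best.x[1], abs=1e-5)

    def test_weighted_residual_orthogonality(self):
        _, G, P, jc = _sim_joint(7)
        fit = fit_pldmr(G, P, jc=jc)
        vc = VarianceComponents(fit.mu_alpha_hat, fit.r2_hat * fit.sigma_y2_hat,
                                fit.sigma_y2_hat)
        W = weight_matrix(vc, jc)
        resid = jc.Gamma_hat - fit.mu_alpha_hat - fit.beta_hat * jc.gamma_hat
        scale = np.linalg.norm(W) * np.linalg.norm(resid)
        assert abs(np.ones(jc.m) @ W @ resid) < 1e-8 * scale
        assert abs(jc.gamma_hat @ W @ resid) < 1e-8 * scale


class TestFitPLDMRTrue:
    def test_zero_pleiotropy_equals_ldmr(self):
        cfg, G, P, jc = _sim_joint(9)
        vc = VarianceComponents(0.0, 0.0, cfg.sigma_y**2)
        ft = fit_pldmr_t(G, P, vc, jc=jc)
        fl = fit_ldmr(G, P, jc=jc)
        assert ft.beta_hat == pytest.approx(fl.beta_hat, abs=1e-10)

    def test_identity_weight_equals_ols(self):
        # engineered eigensystem with constant eigenvalues makes W a scalar
        # multiple of I, so the fit must equal the simple regression line
        prng = np.random.default_rng(3)
        m = 6
        jc = JointCoefs(
            gamma_hat=prng.uniform(0.5, 4, m), Gamma_hat=prng.normal(size=m),
            gram=2.0 * np.eye(m), eig_Q=np.eye(m), eig_lambda=np.full(m, 0.5),
        )
        vc = VarianceComponents(0.0, 0.25, 2.0)
        ft = fit_pldmr_t(None, None, vc, jc=jc)
        fa = fit_pldmr_a(jc)
        assert ft.beta_hat == pytest.approx(fa.beta_hat, abs=1e-10)
        assert ft.mu_alpha_hat == pytest.approx(fa.mu_alpha_hat, abs=1e-10)

    def test_matches_brute_force_gls(self):
        cfg, G, P, jc = _sim_joint(13)
        vc = VarianceComponents(cfg.mu_alpha, cfg.sigma_alpha**2, cfg.sigma_y**2)
        ft = fit_pldmr_t(G, P, vc, jc=jc)
        W = weight_matrix(vc, jc)
        mu0, beta0, se0 = gls_line_oracle(jc.Gamma_hat, jc.gamma_hat, W)
        assert ft.beta_hat == pytest.approx(beta0, abs=1e-10)
        assert ft.mu_alpha_hat == pytest.approx(mu0, abs=1e-10)
        assert ft.se_beta == pytest.approx(se0, rel=1e-8)


class TestFitLDMR:
    def test_closed_form_matches_printed_display(self):
        _, G, P, jc = _sim_joint(17)
        fl = fit_ldmr(G, P, jc=jc)
        S = jc.gram
        J = np.ones((jc.m, jc.m))
        denom = float(np.ones(jc.m) @ S @ np.ones(jc.m))
        A = S - S @ J @ S / denom
        beta0 = (jc.gamma_hat @ A @ jc.Gamma_hat) / (jc.gamma_hat @ A @ jc.gamma_hat)
        assert fl.beta_hat == pytest.approx(beta0, abs=1e-12)

    def test_equals_gram_weighted_gls(self):
        _, G, P, jc = _sim_joint(19)
        fl = fit_ldmr(G, P, jc=jc)
        mu0, beta0, se_unit = gls_line_oracle(jc.Gamma_hat, jc.gamma_hat, jc.gram)
        assert fl.beta_hat == pytest.approx(beta0, abs=1e-10)
        assert fl.mu_alpha_hat == pytest.approx(mu0, abs=1e-10)
        # se scales the unit-weight GLS se by sqrt(sigma_y2_hat)
        assert fl.se_beta == pytest.approx(se_unit * np.sqrt(fl.sigma_y2_hat), rel=1e-8)

    def test_noiseless_exact(self, rng):
        n, m, beta, mu_alpha = 150, 5, 0.07, -0.1
        G = GenotypeMatrix(rng.integers(0, 3, size=(n, m)).astype(float))
        Gc = G.center().values
        x = Gc @ rng.uniform(0.5, 4, m) + rng.normal(size=n)
        y = Gc @ (mu_alpha * np.ones(m)) + beta * x
        fl = fit_ldmr(G, PhenotypePair(x, y))
        assert fl.beta_hat == pytest.approx(beta, abs=1e-10)


class TestFitPLDMRApprox:
    def test_exact_line(self, small_joint):
        jc = small_joint
        jc2 = JointCoefs(
            gamma_hat=jc.gamma_hat, Gamma_hat=0.1 + 0.05 * jc.gamma_hat,
            gram=jc.gram, eig_Q=jc.eig_Q, eig_lambda=jc.eig_lambda,
        )
        fa = fit_pldmr_a(jc2)
        assert fa.beta_hat == pytest.approx(0.05, abs=1e-10)
        assert fa.mu_alpha_hat == pytest.approx(0.1, abs=1e-10)

    def test_textbook_formulas_on_hand_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        jc = JointCoefs(
            gamma_hat=x, Gamma_hat=y, gram=np.eye(5),
            eig_Q=np.eye(5), eig_lambda=np.ones(5),
        )
        fa = fit_pldmr_a(jc)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        se = np.sqrt(resid @ resid / 3.0 / sxx)
        assert fa.beta_hat == pytest.approx(slope, abs=1e-12)
        assert fa.mu_alpha_hat == pytest.approx(intercept, abs=1e-12)
        assert fa.se_beta == pytest.approx(se, rel=1e-12)

    def test_large_n_agreement_with_full_pldmr(self):
        # at n = 20,000 the Gram term sigma_y2*(G'G)^{-1} is two orders of
        # magnitude below sigma_alpha2, so the MLE weights are near-uniform
        # and the OLS approximation tracks the full fit (interior-r2 case)
        _, G, P, jc = _sim_joint(23, n=20000, m=25, rho_g=0.3)
        fa = fit_pldmr_a(jc)
        fp = fit_pldmr(G, P, jc=jc)
        assert abs(fa.beta_hat - fp.beta_hat) < 0.1 * fp.se_beta


class TestSummaryMethods:
    def test_egger_exact_line_floors_overdispersion(self):
        gamma = np.array([1.0, 2.0, 3.0, 4.0])
        mc = MarginalCoefs(gamma, 0.2 + 0.5 * gamma, np.full(4, 0.1))
        fe = fit_mr_egger(mc)
        assert fe.beta_hat == pytest.approx(0.5, abs=1e-10)
        assert fe.overdispersion == 1.0

    def test_egger_equal_weights_equals_unweighted(self, rng):
        gamma = rng.uniform(0.5, 4, 8)
        Gam = 0.1 + 0.05 * gamma + rng.normal(scale=0.2, size=8)
        mc1 = MarginalCoefs(gamma, Gam, np.full(8, 0.37))
        fe = fit_mr_egger(mc1)
        X = np.column_stack([np.ones(8), gamma])
        coef, *_ = np.linalg.lstsq(X, Gam, rcond=None)
        assert fe.beta_hat == pytest.approx(coef[1], abs=1e-10)

    def test_egger_matches_weighted_normal_equations(self, rng):
        gamma = rng.uniform(0.5, 4, 10)
        Gam = 0.1 + 0.05 * gamma + rng.normal(scale=0.2, size=10)
        se = rng.uniform(0.05, 0.4, 10)
        fe = fit_mr_egger(MarginalCoefs(gamma, Gam, se))
        W = np.diag(1.0 / se**2)
        mu0, beta0, se_unit = gls_line_oracle(Gam, gamma, W)
        assert fe.beta_hat == pytest.approx(beta0, abs=1e-10)
        assert fe.mu_alpha_hat == pytest.approx(mu0, abs=1e-10)
        assert fe.se_beta == pytest.approx(se_unit * np.sqrt(fe.overdispersion), rel=1e-8)

    def test_ivw_wald_ratio_single_instrument(self):
        mc = MarginalCoefs([2.0], [0.5], [0.1])
        fi = fit_ivw(mc)
        assert fi.beta_hat == pytest.approx(0.25)
        assert np.isnan(fi.p_value)

    def test_ivw_exact_double(self):
        gamma = np.array([1.0, 2.0, 3.0])
        fi = fit_ivw(MarginalCoefs(gamma, 2 * gamma, np.ones(3)))
        assert fi.beta_hat == pytest.approx(2.0, abs=1e-12)
        assert fi.df == 2

    def test_ivw_direct_formula(self, rng):
        gamma = rng.uniform(0.5, 4, 12)
        Gam = 0.05 * gamma + rng.normal(scale=0.1, size=12)
        se = rng.uniform(0.05, 0.4, 12)
        fi = fit_ivw(MarginalCoefs(gamma, Gam, se))
        expected = np.sum(Gam * gamma / se**2) / np.sum(gamma**2 / se**2)
        assert fi.beta_hat == pytest.approx(expected, rel=1e-12)


class TestInference:
    def test_null_value_gives_p_one(self):
        t, p, lo, hi = t_inference(0.05, 0.01, 10, beta0=0.05)
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert lo < 0.05 < hi

    def test_normal_limit(self):
        _, p, _, _ = t_inference(1.96, 1.0, 100000)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_t23_quantile(self):
        _, p, _, _ = t_inference(2.069, 1.0, 23)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            t_inference(1.0, 1.0, 0)

    def test_mrfit_pvalue_consistent_with_t_and_df(self):
        _, G, P, jc = _sim_joint(29)
        for fit in (fit_pldmr(G, P, jc=jc), fit_ldmr(G, P, jc=jc), fit_pldmr_a(jc)):
            assert fit.p_value == pytest.approx(2 * stats.t.sf(abs(fit.t_stat), fit.df), rel=1e-10)
            assert fit.t_stat == pytest.approx(fit.beta_hat / fit.se_beta, abs=1e-10)
            assert fit.ci_low < fit.ci_high


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [2.0, -0.5])
    def test_outcome_scaling_scales_beta_and_se(self, c):
        cfg, G, P, jc = _sim_joint(31)
        P2 = PhenotypePair(P.exposure, c * P.outcome)
        jc2 = joint_coefs(G, P2)
        mc, mc2 = marginal_coefs(G, P), marginal_coefs(G, P2)
        vc = VarianceComponents(cfg.mu_alpha, cfg.sigma_alpha**2, cfg.sigma_y**2)
        vc2 = VarianceComponents(cfg.mu_alpha, c**2 * cfg.sigma_alpha**2, c**2 * cfg.sigma_y**2)
        pairs = [
            (fit_pldmr(G, P, jc=jc), fit_pldmr(G, P2, jc=jc2)),
            (fit_pldmr_t(G, P, vc, jc=jc), fit_pldmr_t(G, P2, vc2, jc=jc2)),
            (fit_ldmr(G, P, jc=jc), fit_ldmr(G, P2, jc=jc2)),
            (fit_pldmr_a(jc), fit_pldmr_a(jc2)),
            (fit_mr_egger(mc), fit_mr_egger(mc2)),
            (fit_ivw(mc), fit_ivw(mc2)),
        ]
        for f1, f2 in pairs:
            assert f2.beta_hat == pytest.approx(c * f1.beta_hat, rel=1e-5), f1.method
            assert f2.se_beta == pytest.approx(abs(c) * f1.se_beta, rel=1e-5), f1.method
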