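# Methods

## The model

`pldmr` estimates the causal effect of an exposure on an outcome from
individual-level data, using genetic variants as instruments, while
allowing two of the classical instrumental-variable assumptions to fail in
a structured way: variants may act on the outcome directly (pleiotropy)
and may be correlated with each other (linkage disequilibrium, LD).

For *n* individuals, let **G** (n x m) be the column-centered additive
genotype matrix, **X** and **Y** the centered exposure and outcome. The
structural model is

    X = G gamma + eps_X
    Y = G alpha + X beta + eps_Y,

with `alpha ~ N(mu_alpha 1, sigma_alpha^2 I)` a *random* pleiotropic effect
(directional when `mu_alpha != 0`) and `(eps_X, eps_Y)` bivariate normal
per individual with correlation `rho` — all confounding is absorbed into
that error correlation. The target is `beta`.

Let `gamma_hat = (G'G)^{-1}G'X` and `Gamma_hat = (G'G)^{-1}G'Y` be the
multiple-regression coefficients. Substituting the structural model gives
the coefficient-level regression

    Gamma_hat = mu_alpha 1 + beta gamma_hat + e,   e ~ N(0, W^{-1}),
    W = [sigma_alpha^2 I + sigma_y^2 (G'G)^{-1}]^{-1},

so `beta` is the slope of a generalized least-squares line through the
joint coefficients, with the pleiotropy mean as intercept and a precision
matrix that blends an exchangeable pleiotropy term with the LD structure of
the Gram matrix. With the eigendecomposition `(G'G)^{-1} = Q diag(lam) Q'`
and the variance ratio `r2 = sigma_alpha^2 / sigma_y^2`, everything
diagonalizes in the rotated basis `u = Q'(Gamma_hat - mu_alpha 1 -
beta gamma_hat)`: the log-likelihood is a weighted least-squares criterion
with weights `1/(r2 + lam_k)`.

## Estimators

* **PLDMR** (`fit_pldmr`) — the full fit. The variance ratio `r2` is
  estimated by *restricted* maximum likelihood: the criterion is the plain
  negative log-likelihood plus `(1/2) log det(X'V^{-1}X)` with
  `X = [1, gamma_hat]`, which replaces the ML residual-variance divisor m by
  m - 2 and counteracts the downward bias of ML variance components. At
  each `r2` the line `(mu_alpha, beta)` and `sigma_y2` have closed forms, so
  estimation is a bounded one-dimensional minimization over
  `r2 in [0, 1e4]` (the window widens automatically if the optimum presses
  against it). `r2 = 0` is a legitimate boundary estimate; the point
  estimate then coincides with LDMR's.

  The slope variance is the GLS plug-in
  `[gamma'W gamma - (1'W gamma)^2 / (1'W 1)]^{-1}` at the estimated
  components, inflated by a first-order Kenward–Roger-type adjustment for
  the estimation error of `(sigma_alpha^2, sigma_y^2)`. With only m
  coefficient-level observations this error is material; without the
  adjustment the Wald test is anti-conservative (we measured type-I error
  0.069 instead of 0.05 at m = 25 under strong LD). At the `r2 = 0`
  boundary the adjustment's `sigma_alpha^2` contribution is halved, since a
  one-sided constraint turns the component's sampling distribution into a
  point-mass/half-normal mixture with half the unconstrained variance.
  Inference uses t(m - 2), two-sided.

* **PLDMR_t** (`fit_pldmr_t`) — the same weighted line fit with W built
  from the *true* variance components; the simulation oracle.

* **LDMR** (`fit_ldmr`) — the `sigma_alpha^2 = 0` special case in closed
  form: the Gram-weighted regression of `Gamma_hat` on `gamma_hat` with
  intercept. Its slope variance is scaled by `sigma_y2_hat` = Gram-weighted
  residual sum of squares over m - 2; a variance without that scale factor
  would be dimensionally inconsistent with the general W-weighted form, in
  which W carries `sigma_y^{-2}`.

* **PLDMR_a** (`fit_pldmr_a`) — the large-n approximation. Since
  `G'G = O(n)`, W tends to a multiple of the identity and the fit collapses
  to ordinary least squares of `Gamma_hat` on `gamma_hat` with intercept.

* **MR-Egger / IVW** (`fit_mr_egger`, `fit_ivw`) — the summary-statistic
  baselines on per-variant marginal coefficients, with inverse-variance
  weights `SE(Gamma_tilde)^{-2}`. Egger estimates a multiplicative
  overdispersion floored at 1 (no under-dispersion); IVW pins the intercept
  at zero and uses the fixed-effect standard error with t(m - 1).

### Numerical choices

* Gram matrices with condition number above 1e12 are rejected with an error
  naming the most collinear columns; LD pruning is a modelling decision the
  user must make, not something to paper over with ridge terms.
* The symmetric eigendecomposition is computed once per dataset and cached;
  eigenvalues are sorted descending and each eigenvector's first
  non-negligible entry is made positive, so results are bit-reproducible
  across runs.
* Marginal-slope standard errors divide the residual sum of squares by
  n - 1 (one slope, no intercept on centered data).
* Exact-fit data drive the profiled `sigma_y2` to a floor (1e-30); the fit
  is returned with `converged=False` and the line parameters recovered to
  machine precision.
* When the restricted profile is flat in `r2` (large n: `sigma_y2 * lam`
  is orders of magnitude below `sigma_alpha^2`), the optimizer may stop
  anywhere on the plateau; the product `r2_hat * sigma_y2_hat =
  sigma_alpha^2_hat` and the slope inference are stable there, so plateau
  optima are accepted as-is.

### Known limitations

* With m around 25 the split between `sigma_alpha^2` and
  `sigma_y^2 (G'G)^{-1}` is weakly identified; roughly a fifth to a third of
  null replicates put `r2_hat` on the 0 boundary. The boundary-aware
  variance adjustment keeps the test calibrated there, but interval
  estimates of the variance components themselves should not be trusted at
  this m.
* The adjusted t statistic is calibrated at the 5% tails across all
  pleiotropy/LD settings we test, at the price of being mildly conservative
  in the bulk (its standard deviation is about 0.99 against the t(m - 2)
  reference's 1.05). A plain plug-in statistic shows the opposite trade-off
  (t-shaped bulk, inflated tails under strong LD); we chose tail
  calibration, since that is what type-I error control means.
* The model treats `gamma_hat` as fixed. Its sampling error is correlated
  with the outcome-coefficient error under confounding (`rho != 0`); with
  the strong instruments generated here the effect on `beta_hat` is well
  below Monte-Carlo resolution, but very weak instruments are outside the
  intended regime.

## The simulator

`pldmr.simulate` generates cohorts with the exact structure the estimators
assume, plus realistic genotypes:

1. A Toeplitz latent correlation `Sigma_g[j1, j2] = rho_g^{|j1-j2|}`
   (AR(1)-type decay; `rho_g` = 0 / 0.3 / 0.6 give no, low and high LD).
2. Latent normals `z_i ~ MVN(0, Sigma_g)` mapped through the standard
   normal CDF to uniforms (Gaussian copula).
3. Dosage `G_ij` = the smallest k in {0, 1, 2} whose Binomial(2, MAF_j) CDF
   reaches the uniform — Hardy-Weinberg marginals with copula-induced LD.

Defaults define the package's reference study conditions:
`MAF_j ~ U[0.2, 0.4]`, `gamma_j ~ U[0.5, 4]`, `sigma_X = sigma_Y = 2`,
`rho = 0.5`, m = 25, nominal level 0.05. MAF and gamma are redrawn each
replicate (averaging over instrument-strength configurations); a config
switch fixes them per scenario instead. One seeded generator per replicate
consumes streams in a fixed order (MAF, copula normals, gamma, alpha,
errors), so datasets are bit-identical given (config, seed). Columns that
come out monomorphic (possible at small n * MAF) trigger a whole-matrix
redraw so the LD structure is preserved.

What the simulator does *not* emulate: real haplotype block structure
(LD here decays geometrically and uniformly), MAF-dependent effect sizes,
assortative mating or population structure, case-control ascertainment,
genotyping error or missingness (missingness enters only through the QC
layer's file formats). Passing tests therefore demonstrate correctness
under the stated model, not robustness to those real-data features.

## The experiment harness

`run_scenario` simulates `n_reps` independent replicates (default 2,000, giving
a Monte-Carlo SE of about 0.005 on a 5% rejection rate; pass a larger
`n_reps` for publication-grade runs) and aggregates per method: rejection rate at the
nominal level with its binomial MC SE, mean estimate, empirical SD of the
estimates, and mean model-based SE. The individual-level estimators see
the full sample; MR-Egger and IVW are served summary statistics from a
two-sample design (seeded permutation, exposure slopes from the first
half, outcome slopes and SEs from the second) because that is the setting
they assume. Per-method failures are counted in `n_failed` and excluded
from aggregates, never silently dropped. `grid` writes one tidy TSV row
per scenario x method and resumes by a stable hash of the canonicalized
config.

## The QC layer

For real cohort files the preprocessing order is fixed and logged:
variants with more than 20% missing calls are dropped and the remainder
mean-imputed (flagged per variant); a 1-df chi-square Hardy-Weinberg test
(exclusion below p = 1e-6 by default; the threshold is a flag) screens the
rest; phenotypes are residualized on covariates (optionally after a log
transform, with transform-then-residualize order); instruments are chosen
by a single multiple regression of the exposure on all candidates
(default p < 5e-8, positively associated variants only, both exposed as
flags); finally everything is centered. The QC report records one decision
row per input variant and conserves counts across stages.
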