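# Methods

This note documents the data-generating process, the estimation machinery,
the evaluation metrics and the numerical choices behind `dynmix`, in the
spirit of a model-documentation page: what is computed, under which
assumptions, and what a green test does and does not establish.

## Data-generating process

A population of `n_clinics` clinics (default 500) is generated as follows.

**Clinic sizes.** `N_i = ceil(exp(Normal(mu_N, sigma_N^2)))`, defaults
`mu_N = ln 65`, `sigma_N = ln 2`: a log-normal with median 65, yielding many
small clinics and a few very large ones (sizes roughly 10–500). Sizes are
ranked into quintiles 1–5 (ties broken by clinic id, so partitions are
deterministic; with 500 clinics each quintile holds exactly 100).

**Clinic random effects.** `(b_0i, b_1i, b_2i) ~ N(0, T)` with
`T[kk] = tau_k^2` and all off-diagonal correlations equal to `rho`
(default 0.3). Components with `tau_k^2 = 0` are dropped from the
multivariate draw and returned as exact zeros, because the full T is
singular whenever a tau vanishes; positive semidefiniteness of the active
submatrix is enforced at parameter construction. By convention `tau_2^2`
is 0 when `beta2 = 0` and equals `tau_1^2` otherwise (overridable).

**Volume effect.** `f(N_i) = Omega (ln N_i - mean(ln N_i))` with `Omega`
the reciprocal of the *empirical* (ddof = 1) standard deviation of
`ln N_i`, so that `mean(f) = 0` and `sd(f) = 1` hold exactly in every
population. The theoretical scale `sigma_N` is deliberately not used: the
ceiling in the size draw shrinks the realized log-size SD to about 0.686
(Monte-Carlo over 1e6 draws), so `Omega ≈ 1.457` rather than
`1/ln 2 ≈ 1.443`. If all sizes are identical, f is returned as all zeros
with a warning.

**Outcome.** `Y_ij = beta0 + b_0i + (beta1 + b_1i) X1 + (beta2 + b_2i) X2
+ gamma f(N_i) + quad1 X1^2 + quad2 X2^2 + eps`, with `X1, X2 ~ N(0,1)`,
`beta0 = 0`, `beta1 = 1` (so `beta2` and `gamma` read as effects relative
to X1). The stored `mu_true` is this expression minus `eps`; `y = mu_true
+ eps` holds exactly.

**Residual calibration.** `sigma_eps^2 = alpha/(1-alpha) * V`, with `V`
the variance of the linear predictor computed *analytically* under
independence of the covariates, random effects and volume effect (all
cross-covariances vanish because E[X] = 0):

    V = tau0^2 + (beta1^2 + tau1^2) + (beta2^2 + tau2^2) + gamma^2
        + 2 quad1^2 + 2 quad2^2.

The analytic route makes the calibration exact and replicate-independent.
The quadratic (misspecification) terms contribute `Var(c X^2) = 2 c^2` and
also shift the outcome mean by `c`; the shift is part of the true
conditional mean and is not removed. At the base combination
(`tau0^2 = 1, tau1^2 = 0.25, beta2 = gamma = 0, alpha = 0.2`) this gives
`V = 2.25`, `sigma_eps = 0.75`, hence the reference ratios
`tau0/sigma_eps = 4/3` and `tau1/sigma_eps = 2/3`.

**Randomness.** Four named substreams (sizes, random effects, covariates,
residuals) are spawned in a fixed order, so changing one sweep parameter
never perturbs unrelated draws, and a given (parameters, seed) pair yields
a bit-identical population.

## Estimation

The three model families (fixed-effects linear; random intercept; random
intercept + slope; each optionally with quintile-of-size as a 5-level
categorical fixed effect, treatment-coded against quintile 1) are identity
-link linear mixed models fit by restricted maximum likelihood.

The fitter profiles the fixed effects and residual variance out of the
restricted likelihood and parameterizes the relative covariance
`Psi = G/sigma^2` through its Cholesky factor with log-scale diagonal.
The profiled deviance is evaluated from per-cluster sufficient statistics
(`[X, y]'[X, y]`, `Z'[X, y]`, `Z'Z` per cluster) via the Woodbury
identity, so one evaluation costs O(m) for m clusters regardless of the
number of rows — this is what makes ~80 refits per dynamic replicate on up
to ~35,000 rows affordable. Optimization is Nelder-Mead (xatol 1e-9,
fatol 1e-10), retried once from an inflated-diagonal start if the default
start fails; if both fail the fit falls back to the fixed-effects-only
solution and is flagged. Fitting is deterministic: identical data give
identical results.

**Covariance regularization.** Mirroring non-informative-prior Bayesian
LMM estimation, the REML deviance carries a weak Wishart-style penalty
`-(nu - q - 1) log|G|` with `nu = q + 2.5` (coefficient 1.5), where q is
the number of random effects. The penalty bounds `G` away from
singularity (boundary estimates otherwise occur with 20 clusters,
especially when a random slope is absent from the generating process).
`wishart_df = q + 1` disables it; tests verify that the penalized
estimates match an independent dense-matrix maximization of the same
objective to 1e-3 on tiny instances, that unpenalized estimates match
statsmodels MixedLM, and that the penalty's influence vanishes as data
grow. The exact hyperparameter is a design choice; nothing downstream is
sensitive to it at the sample sizes used.

**Prediction.** `x'beta + z'b_i` with `b_i` the empirical-Bayes
conditional mode (BLUP) for clinics present in the fitting data and
`b_i = 0` (the hypothetical mean cluster) otherwise. Quintile levels
unseen at fit time contribute the reference level, i.e. 0 (their design
columns are dropped at fit time and their coefficients reported as exact
zeros).

## Dynamic updating

The testing sample (all patients of the 480 non-training clinics) is
visited in one global uniform-random permutation. After each full block of
`theta` predictions, each predicted patient's outcome joins the training
data independently with probability `p_incorporate` (default 0.8,
emulating loss to follow-up; a skipped patient is never revisited), and
every model is refit from scratch on the accumulated data. The final
partial block is predicted but triggers no refit (a refit there could not
affect any prediction). All model specifications share the permutation and
the incorporation draws within a replicate — a paired design that removes
between-model Monte-Carlo noise.

Two bookkeeping choices worth knowing:

- `cycle_index` in a trace is the *block schedule index*
  `floor(order_index/theta)`; actual refits (including refits skipped
  because no new data arrived, and fallbacks to the previous cycle's fit
  when estimation collapses) are recorded in the refit log.
- Because fitting is deterministic and stateless (no warm starts), the
  dynamic model at any cycle is bit-equivalent to a static fit on the
  accumulated training set; a test verifies this snapshot equivalence.

Static evaluation is the `theta = None` special case (one fit, never
updated), and is invariant to `theta` by construction.

## Evaluation

MAE is computed over whichever event set is being scored (training sample,
testing sample, a quintile, a within-clinic index). RI divides the model's
MAE improvement over the intercept-only null by the true model's
improvement; the null prediction (the training-sample mean outcome) is fit
once and never updated, even for dynamic models, so RI stays comparable
across models and update schedules. Per-quintile RI restricts all three
MAEs to the quintile's events while keeping the baseline *predictors*
global. Because all models share the same realized residuals, RI is
insensitive to rescaling `sigma_eps` (tested).

**Learning curves.** For the j-th prediction made at a clinic, absolute
errors are pooled over clinics within each replicate, converted to RI with
that replicate's (phi_0, phi_1), and averaged across replicates with count
weights (pooling-first; recorded in the curve's metadata). Indices whose
pooled count falls below 5% of the j = 1 count are truncated — small-count
tails are noise-dominated. The plateau is the mean RI over the last 20% of
supported indices, and the "80% of gains" index is the smallest j with
`RI(j) >= RI(1) + 0.8 (plateau - RI(1))`; a flat or falling curve returns
j* = 1 with a degenerate flag.

## Replication and what the tests establish

The original study used 1,000 replicates per cell. The package defaults to
desk-scale replication: 200 replicates for population characteristics and
in-sample results (Monte-Carlo SE of the in-sample RI means: ~0.004–0.008),
100 for static out-of-sample results, and 20 full-scale dynamic replicates
(the dominant cost, ~17 s each on one CPU). Comparisons use tolerance
bands of three Monte-Carlo standard errors of the reported spreads.
Reduced replication reproduces means, not the reported SDs or density
shapes; single-replicate values fluctuate by several points of RI.

The generator emulates the stated world exactly (normal effects, normal
covariates, missingness completely at random, a single known predictor).
It does not emulate non-normal heterogeneity, informative missingness,
binary/survival outcomes, or covariate-dependent incorporation — green
tests say nothing about those settings. Learning-curve indices at 20
replicates are stable to about ±1–2 predictions; the base-cell indices
(~7 and ~9 for the two mixed models; ~17 when the residual share is
raised to 0.5) are reproduced at that resolution.
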