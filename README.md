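# dynmix

Dynamic mixed-effects prediction models for clustered data: a simulator,
fitter and evaluation harness for studying how much prediction accuracy a
clinical prediction model gains when it is *dynamically updated* as it is
used across many clinics.

## The problem

Clinical prediction models are usually developed in a handful of centres and
then applied everywhere. In clustered populations — patients within clinics,
hospitals, practices — outcomes and covariate effects vary across clusters,
and a model fit once on a small derivation sample ("static" modelling)
cannot anticipate the idiosyncrasies of clinics it has never seen: a linear
mixed model can only predict novel clusters at the hypothetical mean cluster
(random effects b_i = 0). A *dynamic* mixed-effects model makes predictions
with the best currently available fit, captures the outcomes of patients it
has predicted, and is periodically refit on the growing sample — so novel
clinics become known clinics, and predictions start using cluster-specific
random effects.

## The model

Patients j in clinics i are simulated from a linear mixed model

    Y_ij = b_0i + (beta1 + b_1i) X_1ij + (beta2 + b_2i) X_2ij
           + gamma * f(N_i) + eps_ij

with clinic sizes N_i ~ ceil(exp(N(mu_N, sigma_N^2))) (log-normal: many
small clinics, a few very large ones), clinic-level random effects
(b_0i, b_1i, b_2i) ~ N(0, T) with common correlation rho, a standardized
log-volume effect f(N_i) (the "volume–outcome relationship"), and
eps_ij ~ N(0, sigma_eps^2) calibrated analytically so the residual carries a
fixed share alpha of the total outcome variance.

Three prediction models are compared, each as a static and a dynamic
variant, optionally with clinic-size quintile as a categorical fixed effect:

1. a fixed-effects linear model `beta1 * X1`;
2. a mixed model with a random intercept;
3. a mixed model with a random intercept and slope.

Mixed models are estimated by profiled REML with a weak Wishart-style
penalty on the random-effects covariance (the analogue of non-informative
Bayesian LMM estimation), and cluster effects are empirical-Bayes BLUPs.
Dynamic updating refits all models after every `theta` predictions,
incorporating each predicted patient's outcome with probability 0.8
(emulating loss to follow-up).

Accuracy is measured by mean absolute error (MAE) and reported as the
relative improvement over the intercept-only null, scaled by the true
model's improvement:

    RI = (phi_0 - phi_model) / (phi_0 - phi_1)

where `phi_0` is the null model's MAE and `phi_1` the MAE of the true
conditional mean; RI = 0 is null-equivalent, RI = 1 oracle-equivalent.

## Worked example

```python
import numpy as np
import dynmix as dm

params = dm.SimulationParams()            # the base world: 500 clinics, median size 65
pop = dm.generate_population(params, seed=1)
ids = dm.select_training_clinics(pop, np.random.default_rng(2))
train = pop.patients_of(ids)

fit = dm.ClusteredLMM(train, dm.random_intercept_slope()).fit()
print(fit.summary())

traces = dm.run_dynamic(pop, ids, dm.standard_specs(),
                        theta=500, p_incorporate=0.8,
                        rng=np.random.default_rng(3))
res = dm.score_trace(traces["random_slope"], train["y"].mean())
print(f"dynamic intercept+slope RI: {res.ri:.3f}")
```

which prints (numbers from this exact seed):

```
Clustered LMM results: random_slope
==========================================================
fixed terms:  intercept, x1
random terms: intercept, x1
n obs: 1244    n clusters: 20    converged: True
----------------------------------------------------------
coef              estimate     std err
intercept          -0.4466      0.1901
x1                  0.8821      0.1146
----------------------------------------------------------
residual variance sigma^2: 0.5532
random-effects covariance G:
      0.7064      0.1255
      0.1255      0.2464
dynamic intercept+slope RI: 0.947
```

Read: from 20 clinics (1,244 patients) the fit recovers the generating
values (beta1 = 1, G = [[1, 0.15], [0.15, 0.25]], sigma^2 = 0.5625) within
sampling error, and the dynamically updated model achieves 95% of the
accuracy gain the true data-generating model would achieve on ~39,000
out-of-sample patients — a static version of the same model reaches only
about a third of it.

The same machinery is scriptable from the shell:

```bash
dynmix simulate-population --seed 1 --out pop/
dynmix run-experiment --config grid.yaml --out results/
dynmix summarize --in results/ --out tables/
```

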