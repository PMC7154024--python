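# trajmix

Latent-class trajectory models for longitudinal data in epidemiology and
biostatistics: when one outcome is measured repeatedly over time on many
subjects — a child's BMI across ages, a parent-reported behaviour across
waves — are there distinct *typologies* of trajectories, how many, who
belongs to which, and how do the resulting classes relate to earlier
exposures and later outcomes?

`trajmix` implements the four related model families such analyses compare,
in one estimation engine:

- **Mixed effects model (MEM)** — a single population:
  `Z_ij = x_ij' β + z_ij' u_i + ε_ij`, with subject-level random
  coefficients `u_i ~ N(0, Ω_u)` around a polynomial mean trajectory.
  Continuous outcomes use Gaussian errors; ordered-categorical outcomes use
  a cumulative-logit latent variable `Z'_ij` with standard-logistic error
  (variance π²/3) cut at thresholds `τ_1 < … < τ_K`.
- **Growth mixture model (GMM)** — a finite mixture of MEMs: latent classes
  `c = 1…C` with probabilities `p_c`, class-specific mean trajectories
  `β^c`, and within-class random variation `Ω_u` (shared) or `Ω_u^c`
  (class-specific).
- **Latent class growth analysis (LCGA)** — a GMM with no within-class
  random variation: fixed class trajectories, residuals independent given
  class.
- **Longitudinal latent class analysis (LLCA)** — LCGA with unconstrained
  time-specific class means (time dummies) instead of a polynomial.

Estimation is maximum likelihood: closed-form marginal normal likelihoods
for the continuous family, Gauss–Hermite quadrature for the ordinal family,
and EM with multiple randomized starts for the mixtures (observed-data
log-likelihood asserted nondecreasing at every iteration). Around the
fitted models the package provides:

- model selection — AIC, BIC, sample-size-corrected c-BIC, relative
  entropy, the parametric bootstrap likelihood ratio test (BLRT), and a
  comparison table that flags classes below 5% of the sample;
- association of classes with an antecedent covariate (relative risk
  ratios) or a distal outcome (mean differences), by the joint **1-step**
  model, the bias-adjusted **3-step** estimators (ML correction through the
  classification-error matrix for covariates, inverse-error weighting for
  distal outcomes), or the uncorrected naive comparison;
- diagnostics — distributions of subject-level coefficients across models,
  posterior-weighted residual skewness, class cross-tabulations;
- a fully seeded simulator for all families, with covariate-linked
  membership, class-linked distal outcomes, monotone missing-at-random
  dropout, and presets emulating a birth-cohort BMI-like continuous outcome
  and a fussy-eating-like 3-category ordinal outcome.

## Worked example

Three latent trajectory classes of a BMI-like outcome across ages 8–16: a
dominant flat class, a steeply rising minority and a higher-level minority,
with class membership linked to a standardized antecedent covariate
(log-RRRs 0.10 and 0.28) and a right-skewed distal outcome whose
log-scale class means are 1.00, 1.30 and 1.35.

```python
from trajmix import (DesignSpec, MixtureSpec, SimulationScenario,
                     TrajectoryMixture, compare_models,
                     threestep_covariate, threestep_distal, simulate)

design = DesignSpec(degree=1, centre=8.0)
scenario = SimulationScenario(
    n_subjects=800, design=design,
    grid=(8.0, 10.0, 12.0, 14.0, 16.0),
    class_fixed=[[16.0, 0.10], [15.0, 0.80], [19.5, 0.45]],
    membership_gamma=[[0.0, 0.0], [-1.90, 0.10], [-2.20, 0.28]],
    resid_var=1.0, with_covariate=True,
    distal_means=[1.00, 1.30, 1.35], distal_sd=0.35)
data, truth = simulate(scenario, seed=11)

fits = [TrajectoryMixture(data, MixtureSpec(C, design)
        ).fit(n_starts=6, seed=C) for C in (1, 2, 3, 4)]
table, rec = compare_models(fits)
print(table[["n_classes", "loglik", "BIC", "entropy",
             "smallest_class_pct"]].round(2).to_string(index=False))
print("recommended:", rec["n_classes"], "classes")

best = fits[rec["n_classes"] - 1]
print(threestep_covariate(best, truth["covariate"].to_numpy()).summary())
print(threestep_distal(best, log_scale=True).summary())
```

This prints (machine output):

```
 n_classes   loglik      BIC  entropy  smallest_class_pct
         1 -8181.45 16382.95      NaN              100.00
         2 -6936.22 13912.54     0.97               18.17
         3 -6220.96 12502.08     1.00                8.12
         4 -6220.92 12522.06     0.61                8.12
recommended: 3 classes
covariate association (3step), reference class 1, N=800
 class  class_pct  log_rrr       se    ci_low  ci_high      rrr  rrr_ci_low  rrr_ci_high
     2      8.125 0.048190 0.131713 -0.209963 0.306342 1.049370    0.810614     1.358447
     3     12.000 0.197077 0.111281 -0.021030 0.415184 1.217838    0.979190     1.514650
distal association (3step), reference class 1, N=800
 class  class_pct  mean_difference       se   ci_low  ci_high
     2      8.125         0.327794 0.044665 0.240252 0.415336
     3     12.000         0.233934 0.038390 0.158690 0.309177
```

Read: BIC bottoms out at the generating three classes, which are perfectly
separated (entropy 1.00) with class shares matching the generative
marginals (≈ 80/12/8%; the two minority labels come out swapped, as labels
are arbitrary). The corrected RRRs per 1 SD of the covariate track the
generating membership effects within sampling error, and the distal
log-scale mean differences (0.33 and 0.23 against generating contrasts of
0.35 and 0.30) recover the class–outcome link after accounting for
classification error.

A command-line front end mirrors the pipeline
(`trajmix simulate | fit | select | associate | report`); see
`trajmix --help`.

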