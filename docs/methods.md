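# Methods

This note records the models `trajmix` fits, the estimation machinery and
its numerical choices, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
choice existed.

## Models

All four families describe repeated measures `Z_ij` of one outcome on
subjects `i = 1…N` at times `t_ij`, and differ only in how they decompose
between-subject variation.

**Mixed effects model (MEM).** For a continuous outcome,

    Z_ij = x_ij' β + z_ij' u_i + ε_ij,
    u_i ~ N(0, Ω_u),   ε_ij ~ N(0, σ²_ε)  (or σ²_εj per grid time),

where `x_ij` is a polynomial basis in time (columns `1, t, t², …`,
optionally centred) and `z_ij` the subset of those columns carrying random
coefficients (dimension capped at 3: intercept, linear, quadratic). The
marginal likelihood per subject is multivariate normal with covariance
`V_i = Z_i Ω_u Z_i' + diag(σ²)` and is evaluated in closed form, grouped by
observed-time pattern for vectorization.

For an ordered-categorical outcome with K+1 categories, a latent
`Z'_ij = x_ij' β + z_ij' u_i + ε_ij` with standard-logistic `ε`
(mean 0, variance π²/3) is cut at thresholds `τ_1 < … < τ_K`:
`Z_ij = k` iff `τ_{k-1} < Z'_ij ≤ τ_k`. Identification: the fixed-effect
intercept is set to 0 and all K thresholds are estimated — the standard
cumulative-logit convention; estimating both would leave the location of
the latent scale aliased. There is no free residual variance (the logistic
scale is fixed). The marginal likelihood integrates the random effects out
with a prior-scaled tensor-product Gauss–Hermite rule, 15 nodes per
dimension by default; against a dense trapezoid oracle on a 1-D
unit-variance case the 15-node rule is accurate to ~2e-8, and the accuracy
only improves as fitted random-effect variances shrink. Mode-recentred
("adaptive") quadrature was not needed at these scales.

**Growth mixture model (GMM).** A C-component mixture of MEMs: class
probabilities `p_c` on the simplex, class-specific `β^c`, and a
random-effect covariance either shared (`Ω_u`) or class-specific
(`Ω_u^c`); residual variances likewise shared or class-specific, constant
or time-specific. `constrain_re_zero` pins the covariance at exactly zero
while keeping the GMM parameterization — useful for verifying that a
zero-variance GMM and an LCGA reach the same maximum.

**LCGA** is the `covariance_mode="none"` case: fixed class trajectories,
residuals independent given class. **LLCA** replaces the polynomial with
time dummies (intercept plus indicators for grid positions 2…J), removing
any parametric time trend. With a degree-(J−1) polynomial on a J-point
grid, LCGA and LLCA span the same model space and their maximized
log-likelihoods coincide — an equivalence the test suite checks to 1e-5.

## Estimation

Single-class models are fitted by quasi-Newton (L-BFGS-B, numerical
gradients) on an unconstrained parameterization: log-Cholesky for `Ω_u`
(log on the diagonal), log variances, and `τ_1` plus log-increments for
thresholds. Log-variance parameters are bounded at ±23 on the log scale;
a fit ending at the lower bound is flagged as a degenerate variance.
Standard errors come from the inverse of a numerical observed-information
matrix.

Mixtures are fitted by EM:

- **E-step** on the log scale with max-subtraction; posteriors
  `π_ic ∝ p_c f_c(z_i)`.
- **M-step**: `p_c` = posterior column means. Continuous LCGA/LLCA class
  parameters have the exact closed form (posterior-weighted least squares;
  residual variances as posterior-weighted mean squares, pooled across
  classes and/or times according to the sharing mode). All other cases
  (any GMM; ordinal classes) use a numerical ascent on the
  posterior-weighted marginal likelihood, warm-started at the current
  parameters, with the update accepted only if the objective increased — a
  generalized EM step, so the observed-data log-likelihood is still
  nondecreasing. That monotonicity is asserted at run time at relative
  tolerance 1e-8 and raises if violated. An important corollary
  implemented in the initializer: starting values must respect the sharing
  constraints (e.g. a pooled residual variance when `residual_mode` is
  shared), otherwise the first constrained M-step could legitimately lower
  the likelihood.
- **Starts**: k-means on per-subject summary features (mean level and OLS
  slope), one deterministic quantile split on the subject mean, and
  further k-means starts on feature-jittered copies; each start is seeded
  from the fit seed. A class whose mixing proportion falls below `1/(2N)`
  aborts the start; if every start degenerates the best partial fit is
  returned flagged non-converged.
- **Convergence**: absolute-scaled log-likelihood change below `tol`
  (default 1e-8) or 1000 iterations.
- **Polish**: by default the best EM solution seeds a direct L-BFGS-B
  maximization of the observed-data likelihood (class-probability logits
  included). This sharpens the optimum to the precision the
  family-equivalence checks require; it can only increase the likelihood.

`fit_mixture` with C=1 runs the same EM machinery (the numeric M-step then
being a full single-class ML fit), so its agreement with `fit_mem` is a
genuine cross-check of two optimization routes, not a delegation.

## Model selection

AIC `= −2ℓ + 2k`, BIC `= −2ℓ + k log N`, c-BIC `= −2ℓ + k log((N+2)/24)`
with `N` the number of subjects (the independent units) and `k` counting
free parameters including the C−1 free class probabilities and honouring
shared blocks. Relative entropy
`1 − Σ_ic (−π_ic log π_ic) / (N log C)` with `0·log 0 = 0`; undefined
(NaN) at C=1. `compare_models` flags fits with a class under 5% of the
sample or without convergence and recommends the lowest-BIC unflagged
model (criterion configurable), listing AIC/BIC/c-BIC disagreements.

The BLRT simulates `n_boot` datasets from the fitted C-class model
(complete balanced data on the observed grid, same N — the observed
missingness pattern is not replicated), refits both models per replicate
with a reduced number of starts and without the final polish, and reports
`p = (1 + #{LR* ≥ LR}) / (n_boot + 1)`. Failed replicates are dropped and
counted; above 20% failures the result carries a warning flag.

## Association with external variables

Modal assignment is an error-prone measurement of the true class; the
classification-error matrix `D[t, a] = P(assigned a | true t)` is estimated
from posterior mass: `D[t, a] = Σ_{i: a_i = a} π_it / Σ_i π_it`.

- **Antecedent covariate (3-step, ML variant)**: multinomial-logistic
  regression of the *true* class on the covariate, with the assignment
  linked to the true class through the fixed `D`; maximized numerically,
  Wald SEs from the numerical observed information. Reported as RRRs per
  unit of the (standardized) covariate against a reference class
  defaulting to the most frequent one.
- **Distal outcome (3-step, inverse-error weighting)**: subject `i`
  contributes to true class `t` with weight `(D^{-1})[a_i, t]`, whose
  expectation is the true-class indicator; weighted means estimate
  per-true-class outcome means, with influence-function (sandwich-type)
  SEs for the differences. Weights can be negative at low entropy; a
  condition-number warning is attached when `D` is near-singular. The two
  settings get different estimators deliberately: the ML variant assumes
  the membership model, which is natural for an antecedent, while the
  weighting variant leaves the outcome model unspecified, which is safer
  for a distal outcome.
- **1-step**: class probabilities become
  `p_c(x_i) = softmax(γ_0c + γ_1c' x_i)` (reference row fixed at 0) and EM
  gains a weighted multinomial-logistic γ-update. γ standard errors use
  the observed information of the membership block with trajectory
  parameters held at their ML values — a profile-curvature approximation,
  adequate for Wald summaries and cheap.
- Both 3-step estimators reduce exactly to their naive counterparts when
  `D = I`. CIs are Wald 95% throughout; no multiplicity adjustment.
  Subjects missing the covariate or distal outcome are dropped listwise
  and counted.

## Synthetic data

`SimulationScenario` specifies the generative twin of any supported model:
class membership from fixed `p_c` or from a multinomial-logistic link to a
standard-normal covariate; per-class trajectories, random effects and
residual noise; ordinal outcomes via a latent draw with logistic noise cut
at (possibly class-specific) thresholds; a distal outcome drawn normal on
the log scale around class-specific means and exponentiated (right-skewed,
as such outcomes typically are); and monotone MAR dropout whose per-wave
hazard is logistic in the previous *observed* outcome and the baseline
covariate. A mechanism referencing the current unobserved value is
rejected at construction — it would be MNAR. Same scenario + same seed
gives a bit-identical dataset.

Two presets emulate the structure (not the parameters) of a birth-cohort
application:

- **BMI-like**: continuous, 6 waves at ages 8–16, three classes with
  marginal shares ≈ (0.88, 0.07, 0.05) — dominant slow-rising, steeply
  rising, and parallel-high — quadratic on the log scale with a shared 3×3
  random-effect covariance, exponentiated to induce right skew; membership
  linked to the covariate (log-RRR 0.10 and 0.28 for the minority
  classes); per-wave dropout ≈ 8–16%, increasing with the previous value.
- **Fussy-eating-like**: 3-category ordinal, 8 waves at ages 1.3–9.6,
  classes ≈ (0.751, 0.165, 0.084): stable; drifting toward the bottom
  ("did not happen") category; drifting toward the top ("worried")
  category. Latent linear+quadratic trends centred at the first wave,
  shared random intercept (variance 1), class-specific thresholds.

All preset coefficients are the package's own illustrative choices,
selected once for qualitative shape (crossing vs parallel classes,
growing stacked probabilities); they are not calibrated to any restricted
cohort's data, and simulation-based tests therefore validate the
machinery, not any published quantity. Features of real cohort data the
generator does not emulate: intermittent (non-monotone) missingness by
default (available via configuration), consent-driven wave patterns,
measurement error in the covariate, and per-subject observation times off
the common grid.

## Sizes used in the verification suite

The test suite and `scripts/acceptance.py` use deliberately modest problem
sizes chosen to make each property measurable with comfortable margin:
N=200–300 for the family reductions, N=1000 for 3-class recovery and BIC
enumeration (10 replicates over C=1…4), N=2000 with 20 replicates for the
corrected-RRR recovery, N=300 with 20 replicates for the MAR comparison,
and N=150 with 50 bootstrap replicates × 10 null runs for the BLRT. The
low-entropy 1-step scenario uses a 1.1σ class separation (realized entropy
≈ 0.5) with a strong membership effect (log-RRR 2) so the proportion shift
is well above estimation noise.

## Known limitations

- Random-effect dimension is capped at 3 (2 are exercised by the ordinal
  tests); higher dimensions would need sparse-grid or adaptive quadrature.
- Gradients are numerical throughout; fits with many classes and
  time-specific variances are correspondingly slower.
- The 1-step model's γ SEs are profile-curvature approximations (see
  above); fully joint SEs would require the complete information matrix.
- The BLRT bootstrap simulates complete data on the grid; with heavy
  dropout its null distribution is an approximation.
- Class-varying design shapes (different polynomial degrees per class) and
  multivariate outcomes are out of scope.
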