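# Methods

This note documents the statistical model, the estimation choices, the
synthetic-cohort generator, and the simulation experiments that validate
them, together with the design decisions a maintainer would want explained.

## The mediated two-equation system

The analysis models a mixed-longitudinal pediatric cohort: participants
*i* = 1..P measured at 1–4 annual sessions *t*, giving a two-level hierarchy
(sessions within participants). On z-scored variables,

    bone:    Y_it = beta0 + M_it beta1 + Z_it' Theta + gamma_i + eps_it
    muscle:  M_it = omega0 + W_it' Omega + delta_i + mu_it

with participant random intercepts gamma_i ~ N(0, s2_level2),
delta_i ~ N(0, s2_delta) and session residuals eps, mu. Y is bone speed of
sound (radial or tibial), M the site-matched muscle strength (grip for
radius, knee extension for tibia). Z = {NTX, PAQ-C, maturity offset, BMI};
W = {maturity offset, BMI, bone age, WAeq, energy intake}. The two activity
scores appear in different equations deliberately: PAQ-C captures the
loading that acts on bone directly, WAeq the activity that builds muscle.

Assumptions: random effects normal, mean zero, independent of covariates;
cross-equation errors independent. Under that recursive structure the joint
likelihood factorizes, so the equations are fitted separately, each on its
own complete cases (the data have irregular missingness: grip strength is
absent for one whole season, NTX for sessions without a urine sample).
Equation-wise complete-case fitting is the estimand-preserving counterpart
of a joint SEM fit; it does not impute.

### Effect decomposition

For a modulator with muscle path *a* (from Omega), direct bone path *theta*
(from Theta, zero if the modulator is not in the bone equation) and mediator
path *b* = beta1:

* indirect = a·b, SE by first-order delta (Sobel):
  sqrt(b² var_a + a² var_b);
* total = theta + a·b, variance
  var_theta + b² var_a + a² var_b + 2a·cov(theta, b), with cov(theta, b)
  taken from the bone-equation coefficient covariance and cross-equation
  covariances set to zero (the equations are fitted on overlapping but
  different complete-case sets; no joint covariance exists).

Additivity (total = direct + indirect) and the product rule are identities
of this decomposition and are asserted exactly (1e-12) in the tests.
Mediation is classified per modulator: *full* if the indirect effect is
significant (p < 0.05) and the direct path absent or non-significant,
*partial* if both are significant, *none* otherwise. Stars are always
derived from the computed p-values (two-sided normal), never transcribed.

## Estimation

Both equations share one engine: ML for the one-random-intercept Gaussian
model, profiling the likelihood over the variance ratio
lambda = s2_level2/s2_level1. For fixed lambda the per-group marginal
covariance is compound-symmetric and (I + lambda J)^-1 = I − lambda/(1 +
lambda k) J, so the GLS coefficients and s2_level1 are closed-form in group
sums. Numerical choices:

* the profile is assembled in its within/between split
  X'V⁻¹X = Xc'Xc + Σ_g SxSx'/(k(1+lambda k)) — every term positive, so the
  lambda → ∞ limit is computed without catastrophic cancellation, and the
  GLS residual sum of squares is likewise accumulated in positive form;
* lambda is searched on an 81-point geometric grid spanning [1e-8, 1e8]
  plus the boundary lambda = 0, with bounded Brent polish on log(lambda)
  (xatol 1e-10); ties within 1e-8 relative log-likelihood break toward the
  OLS boundary, which resolves the unidentified ridge when every group has
  one observation;
* rows are sorted by a content-based canonical key before accumulation, so
  results are bitwise invariant under input row permutations;
* coefficient covariance is the inverse GLS information at the optimum; no
  Kenward–Roger-type small-sample correction, matching large-sample z
  inference. REML is available by flag (see the Chow test below);
* rank-deficient designs raise an error naming the collinear columns;
  non-convergence is flagged, never silent.

The engine is cross-checked in the tests against (a) a dense grid-plus-
polish maximization of the explicit multivariate-normal likelihood on a
16-observation fixture (agreement 1e-6) and (b) statsmodels MixedLM under
both ML and REML — an independent oracle, not a dependency of the
implementation.

### The pooled two-site model

The pooled fit stacks radial and tibial rows (two per session, each with its
site-matched mediator value) with shared coefficients, a participant random
intercept and an additional session-level random intercept. The session
intercept induces exchangeable cross-outcome correlation within a session —
a one-parameter stand-in for the unstructured cross-outcome residual
covariance of a fully bivariate parameterization, which is not identifiable
from the published description. The realized level-1 cross-outcome residual
correlation is additionally reported descriptively. The two variance ratios
are maximized by a coarse log-grid plus Nelder–Mead with both boundaries
admitted. The stacked GLS estimate is not a coordinate-wise convex
combination of the two site fits; simulations with identical generating
coefficients show it brackets the site estimates up to excursions of a
fraction of a standard error (~0.3 SE typical).

### Standardization conventions

Z-scores use the *population* SD (divisor n) over all pooled post-exclusion
non-null observations of a variable; a {−1, +1} column is then a fixed point
and standardization is idempotent. The affine parameters are attached to the
table's metadata for exact back-transformation. Stratified (by-sex) fits
reuse the pooled scaling: re-standardizing within stratum would put the two
strata on different scales and invalidate coefficient comparison. The
within/between variance decomposition uses the population form in both
components for internal consistency: between-SD is the SD of participant
means, within-SD pools squared deviations from each participant's own mean
over observations (single-session participants contribute zero deviations).
Whether the original analysis standardized before or after exclusions is
not recoverable; standardization here happens after, since only the
analysis set enters the models.

### The between-sex (Chow-type) test

Coefficient equality between independently fitted strata is tested with a
Wald statistic: d = beta_boys − beta_girls, Var(d) = V_boys + V_girls,
d'V⁻¹d ~ chi-square(#coefficients). The classical pooled-F form has no
analogue here (a mixed model has no single residual sum of squares); the
independent-strata Wald test is the standard generalization. The default
coefficient set is the bone equation without the intercept, with an
`exclude` argument (the published usage excludes BMI). One calibration
choice matters: with ~90 participants per stratum, ML residual variances
are biased low and the joint 5-df test rejects at 0.074 instead of 0.05
under the null. Stratum fits for this test therefore use REML (rejection
rate 0.060 over 500 replicates), the standard remedy for variance
estimation at moderate group counts; the cohort-level effect tables keep
ML, matching the large-sample z convention of the main analysis.

## The synthetic cohort generator

There is no public accession for the study data, so the generator is a
first-class, tested component that emulates the study's design and
published statistics:

* **Design**: 180 participants (92 boys), session counts 36/53/72/19 for
  1/2/3/4 annual sessions (434 observations; drawn exactly when the
  configuration is the default, multinomially otherwise), visits laid on a
  7-wave spring/fall calendar with start waves staggered so every
  participant finishes inside the window.
* **Calibration targets**: per-variable mean, within-participant SD and
  between-participant SD from the published summary table.
* **Structural truth**: the published standardized coefficients (total
  cohort) for both equations, shared by the radial and tibial processes;
  all truth is specified on the standardized scale and mapped affinely to
  natural units, because that is the scale the analysis reports.
* **Growth**: age, maturity offset and bone age advance +1 year per annual
  session; the trend's contribution to the within-SD is budgeted against
  the configured within-SD using the realized session counts (a zero
  within-SD budget therefore freezes repeated values, shrinking the trend
  to fit). Between-participant intercepts absorb the remaining variance
  with exact finite-P corrections.
* **Distribution families**: age-like variables, BMI and PAQ-C are
  Gaussian; NTX, WAeq, energy intake and creatinine are lognormal with
  mean and within/between SDs matched exactly in closed form (these are
  strictly positive, right-skewed quantities, and a Gaussian with the
  published moments would cross zero). The endogenous outcomes (grip, knee
  extension, both SOS) must remain linear-Gaussian for the structural truth
  to be exact, so they carry a positivity floor (0.5 in natural units);
  because the knee-extension mean sits only ~2.2 SD above zero, the floor
  would otherwise compress ~2.7% of its variance, so in the default
  auto-calibrated mode the two residual variances and the equation
  intercept are solved per seed by a damped fixed point against the
  realized post-floor moments, making mean, within-SD and between-SD exact
  to floating point. Explicit residual SDs bypass this and use an analytic
  mean compensation instead.
* **Covariate correlation**: covariates are correlated only through their
  participant-level dependence on maturity offset, with loadings
  (bone age 0.85, age 0.90, BMI 0.30, energy 0.25, NTX −0.35, creatinine
  0.40, activity scores 0) chosen once for physiological plausibility —
  skeletal and chronological age track somatic maturity closely, body size
  and intake grow with maturation, resorption markers fall — and exposed
  as configuration knobs, since the source analysis reports no covariate
  covariances.
* **Cross-outcome dependence**: grip/knee (and radial/tibial) share
  participant-level effects with correlation 0.5 and session-level
  residuals with correlation 0.3, so the pooled stacked model has real
  dependence to absorb.
* **Missingness** (applied last, completely at random within its stratum):
  grip strength absent for every observation in one designated fall
  season-year (~10% of observations), NTX and creatinine Bernoulli-missing
  per session at rate 29/434, energy optionally. The published grip counts
  are internally inconsistent (306 with grip vs 406 − 43 = 363), so the
  grip-missing mechanism is a knob rather than a hard-coded count.
* **Exclusion flags**: 6 diabetes / 8 fracture / 11 undetectable-SOS /
  3 missed-visit flags on distinct random observations, so the cascade
  reproduces 434 → 406; undetectable-SOS and missed-visit rows also blank
  the measurements a real visit would lack.

The generation report echoes the realized moments computed on the complete
pre-missingness data — the object the calibration controls; missingness and
exclusions thin the unbalanced design and would otherwise bias the pooled
within-SD estimator downward by ~2% purely through shorter session series.

What the generator does *not* emulate: seasonal bone variation, covariate
measurement error, informative missingness, drop-out correlated with
growth, non-linear growth curves, or site-specific structural coefficients
(both bone sites share the total-cohort truth by default). Passing tests
therefore show that the pipeline recovers the assumed linear-Gaussian
mediated structure at the study's size and missingness — not that real
bone-development data satisfy that structure.

### The tiny oracle fixture

`make_fixture("tiny")` (8 participants × 2 sessions) exists for closed-form
and bootstrap oracles, and is designed for conditioning rather than realism:
balanced within/between variance in every covariate (at 8 groups, a
between-dominated covariate like BMI at the study calibration becomes
nearly unidentified in refits whose variance ratio lands high, which
inflates bootstrap SDs erratically), mutually independent covariates,
strong structural paths, and explicit residual SDs (0.2 session / 0.6
participant) so the two-level structure is pronounced and refitted
variance components stay off the boundary.

## Validation experiments (tests/test_acceptance.py)

* **Arithmetic**: indirect products, totals and the boys–girls difference
  reproduce the published cells at 3-decimal rounding from the printed
  coefficients — restricted to cells whose printed inputs are themselves
  consistent with the printed outputs (a few published cells round from
  unrounded intermediates instead).
* **Likelihood oracle**: the profiled engine matches a dense grid-plus-
  polish maximization of the explicit marginal likelihood to 1e-6 on the
  tiny fixture.
* **Parameter recovery**: 1000 replicates at full study scale (180
  participants, default missingness), fitting the radial system to data
  whose truth is the published coefficients. Replicate data are
  standardized with the generator's *configured* affine parameters, so the
  truth is exact on the fitted scale: re-estimated scale factors would add
  ~3–5% multiplicative noise per path that belongs to scale estimation,
  not to the structural estimator under test. Observed: every path's 95%
  CI coverage within [0.937, 0.958] and |bias| ≤ 0.003 standardized units.
* **Sobel vs bootstrap**: on the tiny fixture, the delta-method SE of each
  indirect effect is within 15% of its SD over 1000 parametric-bootstrap
  refits (observed ratios 0.90–1.02; the delta SE runs slightly low, the
  known direction of the first-order approximation).
* **Type-I error**: the joint between-sex Wald test rejects at 0.060 over
  500 equal-coefficient replicates (nominal 0.05, band [0.03, 0.07]).
* **Mediation pattern**: generated bone age (no direct bone path) is
  classified as fully mediated; maturity offset as partially mediated.

Problem sizes were chosen so the full suite (unit + simulation) completes
in a few minutes on one CPU: 1000 recovery replicates, 500 type-I
replicates, 1000 bootstrap refits, 50 calibration seeds.

## Known limitations

* The delta-method SEs and normal p-values are first-order/large-sample;
  at very small n the Sobel SE underestimates (the bootstrap flag on
  `sobel_bootstrap_sd` quantifies by how much).
* The pooled model's exchangeable cross-outcome correlation is a
  simplification; with strong, outcome-specific residual covariance the
  session-intercept variance can pin at zero while the descriptive
  residual correlation remains positive.
* Complete-case fitting is only valid under missingness at random within
  equations — which the generator satisfies by construction and real
  cohorts may not.
* No multiple-testing correction is applied to the effect tables, matching
  the source convention; with ~20 effects per table, isolated stars should
  be read accordingly.
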