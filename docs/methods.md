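# Methods

## Synthetic study generator

The generator (`fwtrace.synthetic`) emulates the structure of a pooled
multi-cohort aging/AD study. Seven cohorts carry the published participant
counts (830, 757, 127, 974, 1160, 326, 293; total 4467) with per-cohort
baseline-age means/SDs, education, sex ratios, APOE e4 rates and
CU/MCI/AD mixes matching the published participant table. Visit schedules
are Poisson: 1 + Poisson(mean visits - 1) visits, gaps jittered uniformly
within +/-40% of the cohort's mean interval, follow-up capped at 13 years.
The published table gives only visit-count and follow-up summaries, so the
schedule model is loosely calibrated to those; optional monotone dropout
exists but defaults off.

Cognition (memory, executive, language z-composites) follows the mixed
model

    y_dij = mu_d + x_i'beta + g_d * beta_cross * w_i + b0_i
            + (b1_i + g_d * theta * w_i + theta_age * zage_i
               + sum_e phi_e * w_i * endo_ei) * t_ij + eps,

where w_i ~ N(0,1) is a latent white-matter burden, t_ij the interval in
years, (b0, b1) ~ N(0, (0.50, 0.08)^2) random effects and eps ~ N(0,
0.35^2). Domain gains g_d = (1.0, 0.6, 0.5) give the memory-dominant
pattern. Defaults theta = -0.15 and beta_cross = -0.30 place the
effect-carrying feature (fornix FW) at the magnitude of the headline
fornix associations; covariate effects (age, education, sex, diagnosis,
APOE e4) are fixed at plausible z-scale values.

**Feature scale.** Tract x metric features are generated on a standardized
(z) scale rather than physical diffusivity units: every downstream step
(harmonization, scans, variance partitioning) is scale-free, and z-scale
features make injected batch effects and recovered coefficients directly
interpretable. Physical units (mm^2/s) appear only in the DWI phantom
path. Effect-carrying features equal w_i exactly at baseline (plus an age
trend shared by all features) so generating coefficients are recoverable
without measurement-error attenuation; all other features are independent
noise with subject intercept SD 0.70 and visit noise SD 0.71 (a
test-retest reliability near 0.5, deliberately pessimistic).

**Batch effects.** Observed features are gamma_b + biology + delta_b *
visit-noise. The multiplicative effect scales the measurement-noise
component only — the location-scale convention of the harmonization model
itself; scaling the biological signal too would make batch effects
confounded with the covariates the harmonizer must preserve and is not
what a scanner-specific noise floor does. Default one batch per cohort;
multi-batch cohorts assign each participant one batch.

Endophenotypes are correlated with w (hippocampal volume -0.4, SPARE-AD
+0.4); amyloid/tau positivity are thresholded latent Gaussians (rates
0.33 / 0.22, latent correlation 0.3 with w). The converter flag marks
non-CU baseline status, plus 10% of multi-visit CU participants.

## Free-water fit

The single-shell bi-tensor fit is voxelwise nonlinear least squares on
normalized attenuations over (logit f, tissue tensor), water diffusivity
fixed at 3.0e-3 mm^2/s. Two numerical choices matter:

- **Constraint handling.** A first pass optimizes an unconstrained
  Cholesky parameterization (fast and exact when the optimum is interior);
  if the eigenvalues leave the plausibility box [0.1, 2.9] x 1e-3 mm^2/s,
  a second pass re-optimizes with eigenvalues sigmoid-mapped into the box
  and the orientation as a rotation vector. Without the box the pure-water
  voxel is unidentifiable (tissue D -> d_w mimics free water).
- **Degenerate ridges.** Direction-independent signals (isotropic tissue)
  admit a one-parameter family of exact fits. A vanishingly small residual
  penalty (1e-4 * f) selects the smallest-FW member — so an isotropic
  tissue voxel fits f ~ 0 with the correct MDt, and a pure-water voxel
  still fits f ~ 1 because there the data term dominates. The penalty
  biases identifiable fits by < 1e-4 in f.

f is initialized from the mean-ADC heuristic log(S0/mean S_b)/(b d_w) and
D from a log-linear DTI fit of the f-corrected attenuations; three
initializations are tried, stopping early on an exact fit. Convergence:
least-squares xtol 1e-12, at most 500 evaluations per start.

Noiseless recovery on a 200-voxel grid (f in 0..0.8, FA in 0.1..0.8) has
median |f_hat - f| ~ 2e-4; the worst voxels (high f with near-isotropic
tissue) sit on near-degenerate ridges and can err substantially — a known
pathology of voxelwise single-shell estimation. Under Rician noise at SNR
30 the fit is weakly identified and individual voxels are bimodal; the
mean bias stays within 0.05 for a 64-direction shell over a mixed-FA
grid. The spatially regularized variant of the original estimator is not
implemented (documented limitation); exact numerical parity with any
specific implementation is not a goal.

## Atlas and QC

The packaged registry enumerates 48 tracts in 7 type groups (limbic,
association, projection, and transcallosal prefrontal/motor/parietal/
occipital), giving 240 features with the 5 metrics. Mask-based extraction
uses weight-normalized means (binary masks are the weight-1 case); the
synthetic atlas partitions a grid into 48 disjoint masks purely to
exercise the volumetric path.

The outlier filter regresses each feature on baseline age (simple linear
regression, baseline-session values) and excludes a participant — all
sessions — when any feature's standardized residual exceeds 5 SD. The
residual SDs can be frozen from the first pass, making the filter
idempotent by construction.

## Longitudinal ComBat

Per feature, a linear mixed model with the preserve design (age, age^2,
sex, baseline diagnosis, age x converter, age^2 x converter), batch as a
fixed effect under an n-weighted sum-to-zero constraint, and a subject
random intercept. "Participant-specific trajectories" are interpreted as
the random intercept capturing subject offsets, with slope structure
preserved through the age terms; a random-slope option is out of scope.

Empirical-Bayes pooling departs from the classic formula in one respect:
the normal-prior shrinkage of gamma weights each estimate by its own
mixed-model sampling variance, with tau^2 estimated by noise-corrected
method of moments. In longitudinal data the sampling noise of a batch
effect is dominated by between-subject variance, which the classic
row-count weighting ignores — it badly over-shrinks exactly when subjects
are few and visits are many. delta^2 is estimated unbiasedly from
within-subject demeaned residuals (subjects contribute n_i - 1 degrees of
freedom) and shrunk toward an inverse-gamma prior with method-of-moments
hyperparameters. Fewer than 5 features -> no shrinkage. Degenerate
(noise-free) features fall back to OLS so exact small cases behave
exactly.

Batch-effect removal is quantified against a paired counterfactual: the
same seed generates the study with and without the injection, so the
injected component of every batch mean is known exactly and is not
confounded with sampling noise. Sizing note: the irreducible error of the
pooled batch-effect estimate is ~ subject-SD / sqrt(n_subjects x
n_features), so the injection experiment uses 3 x 500 participants and 40
features, where a 0.1 injection can be removed to well under 10%.

## Association scans

Cross-sectional: per-feature OLS at baseline with z-scored continuous
variables and dummy-coded categoricals (references: CU, female, NH White,
APOE non-carrier). Longitudinal: per-feature mixed model with random
intercept + interval slope; the WM x interval Wald z is reported,
matching heatmap-style per-model z values. Interaction scans add the
endophenotype block with every lower-order term and report the 2-way
(cross-sectional) or 3-way (longitudinal) product. Non-convergence falls
back to a random intercept, else the feature is flagged. FDR is BH within
one scan family (all tract x metric combinations for one domain and
term), the narrowest reading of scan-wide correction; pooling across
domains is a caller choice. In recovery tests the outcome/feature scaling
is disabled so coefficients compare directly with generating values;
scaling changes estimates and CIs by a common factor and so preserves
coverage.

Demographic comparisons route each variable through Shapiro-Wilk (per
group) -> Levene -> ANOVA / Welch ANOVA, or Kruskal-Wallis when
non-normal; categoricals use chi-square, or Fisher's exact for 2x2 tables
with an expected count below 5 (larger sparse tables stay with
chi-square, noted in the report). Welch's ANOVA is computed directly from
the standard formula; constant variables are reported untestable.

## Mixed-model engine

The scans and the bootstrap refit the same small LMM thousands of times,
so estimation uses a profiled-REML solver specialized to the random-
intercept(+slope) structure (`fwtrace.lmm`): fixed effects and sigma^2
are profiled out per criterion evaluation via batched 2x2 Woodbury
algebra, leaving a 3-parameter Nelder-Mead search; bootstrap replicates
warm-start from the point fit. It agrees with statsmodels' MixedLM to
optimizer tolerance (the test suite asserts parity against that
independent implementation) at ~25-45x the speed. statsmodels remains the
engine for OLS and inference utilities.

## Variance partitioning

Marginal R^2 is Nakagawa-Schielzeth with the random-slope extension:
var(fixed predictions) over var(fixed) + mean_ij(z' Psi z) + sigma^2.
delta R^2 = R^2(covariates + baseline WM + WM x interval) -
R^2(covariates), in percentage points. The bootstrap resamples
participants with replacement, stratified by cohort, all visits moving
together; CIs are percentile (matching asymmetric reported intervals);
non-converged replicates are dropped and counted, with a warning above
20% (error under strict mode). The identity-resample option returns the
point estimate exactly. ANOVA and pairwise Welch t tests over bootstrap
replicates reproduce the published procedure verbatim; treating
replicates as independent observations is anticonservative, and every
report carries that caveat. The covariate-only R^2 is refit within each
bootstrap run on the same resamples as the full model — delta R^2 is a
paired within-replicate contrast — and each run's base distribution is
what its summary reports; a base distribution shared across features
would decouple the pair and understate replicate-level dependence.

In-sample delta R^2 of a nested larger model is non-negative up to
estimation error, so a small positive null bias (~0.2-0.3 percentage
points at n = 500) is expected and observed.

## Problem sizes

Experiment designs are fixed in `fwtrace.experiments`: the FW grid at 200
voxels; batch-effect injection at 3 x 500 participants x 40 features;
covariate-preservation coverage over 100 replicates of 3 x 60
participants; slope-effect recovery at n = 800 with 3 visits; the null
scan over all 240 features at 3 x 140 participants; the bootstrap null at
n = 500 with 200 replicates; the head-to-head ranking over 14 tracts (2
per type) with 40 replicates each. These sizes make each check's sampling
error small against its tolerance while keeping a full validation pass at
desk scale. The analysis drivers default to 10% of the published cohort
sizes for the same reason.

## Known limitations

- Voxelwise single-shell FW estimation is weakly identified under noise;
  no spatial regularization is implemented.
- Harmonization models a subject random intercept only; true
  batch-varying biological slopes would not be corrected.
- The generator's visit process is independent of cognition (no
  informative dropout by default), cohorts share one feature model, and
  composites are exactly Gaussian — passing tests demonstrate method
  correctness under the stated model, not robustness to real-data
  violations (floor effects, informative missingness, site-by-biology
  interactions).
- Bootstrap ANOVA p-values are anticonservative by construction (see
  above); rankings are the meaningful output.
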