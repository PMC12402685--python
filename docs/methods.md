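# Methods

`erpfa` implements a two-track statistical analysis of event-related
potentials (ERPs) from a 2x2x2 within-participant design — Accent (L1
native vs. L2 foreign-accented speech), sentence Constraint (HC high vs.
LC low) and Face (speaker identity cued by a face or not) — together with
a ground-truth generator that emulates the recording conditions (42
participants, 42 trials per design cell, 60 scalp electrodes, 500 Hz,
1200 ms epochs from -200 to +998 ms).

## Data model and epoch operations

Voltages are microvolts throughout; time axes are milliseconds relative
to word onset.  The canonical grid treats the 1200 ms epoch as 600
samples on the half-open interval [-200, +998] ms, so that decimation to
250 Hz yields exactly 300 samples over the same span.  Baseline
correction subtracts the per-trial, per-electrode mean over [-200, 0) ms
(half-open, excluding the onset sample) and is idempotent.  Resampling is
polyphase with linear-extrapolation padding, which preserves constants
exactly and sub-Nyquist content to within filter ripple; upsampling is
not supported.  Window amplitudes (the N400 input) are means over a
closed window at sample resolution — the default [300, 500] ms includes
both endpoint samples, a choice recorded in every run manifest because
either convention is defensible — averaged over an electrode cluster
(default: centro-parietal Cz, C3, C4, Pz, P3, P4).  Cluster-then-window
and window-then-cluster orders agree because both are means.

Upstream continuous-EEG cleaning (filtering, ICA, artifact rejection,
interpolation) is out of scope: the package consumes cleaned epochs and
records provenance strings only.

## Temporal exploratory factor analysis

Trial-averaged waveforms (one per participant x condition x electrode,
including the pre-stimulus baseline) form the observation matrix of one
accent; time samples are the variables.  The pipeline is:

1. **Factor number — Empirical Kaiser Criterion.**  Eigenvalues
   l_1 >= ... >= l_p of the correlation matrix of the p time samples are
   compared against references
   `ref_j = max((1 + sqrt(p/n))^2 (p - sum_{i<j} l_i)/(p - j + 1), 1)`,
   retaining greedily while l_j > ref_j.  n is the number of observation
   rows (a choice logged in the manifest; participants would be an
   alternative).  Note that with autocorrelated residual noise and
   moderate p/n the criterion intentionally over-retains relative to the
   true component count: the trailing factors are noise-dominated and are
   removed later by the variance filter.
2. **Extraction** from the covariance (not correlation) matrix, so
   loadings stay in microvolts.  Default `uls`: unweighted least squares
   via the iterated principal-factor fixed point (diag(S - LL' - Psi) = 0),
   communalities initialized from squared multiple correlations and
   floored at 0.1% of each variance.  `ml` (EM algorithm) and `pca`
   (eigenvector x sqrt(eigenvalue) columns) are selectable; the estimator
   used is recorded in the manifest because published temporal-EFA
   pipelines are often silent on this point.
3. **Geomin rotation**, oblique by default, eps = 0.01, 30 starts (start
   1 the identity, the rest seeded random orthonormal matrices).  The
   criterion is the row-wise eps-softened geometric mean of squared
   loadings.  Each start first runs a quasi-Newton (L-BFGS) pass on the
   column-normalized oblique transform with the analytic gradient — the
   criterion is extremely flat along the many near-zero noise factors,
   where plain gradient projection crawls — and the gradient-projection
   iteration with Armijo backtracking then certifies the optimum
   (criterion non-increasing; stop when the decrease falls below 1e-7 or
   after 1000 iterations).  Non-converged starts are logged and skipped;
   the best converged start wins, ties broken by start index.
4. **Scores** by the regression (Thurstone) estimator
   `X_c Sigma^{-1} Lambda Phi` with Sigma the model-implied covariance
   (sample covariance selectable), ridge-regularized with a logged jitter
   if singular.  Score columns are standardized, so score times peak
   loading is a microvolt amplitude.
5. **Variance explained** per factor as
   `sum_t lambda_tk s_tk / trace(S)` with structure S = Lambda Phi (the
   pattern x structure accounting; for an orthogonal solution this is the
   eigenvalue share, and a full-rank principal-component solution totals
   exactly 100%).  Factors explaining more than 3% (strict) are retained.
6. **Sign alignment**: each factor is oriented so its largest-|loading|
   sample is positive, with the score column flipped in tandem —
   negative-going components (N400) then appear as negative amplitudes
   through negative scores, and the model-implied covariance is
   untouched.  The peak is the signed loading at maximal absolute value,
   so a negative component has a negative peak loading.
7. **Component summaries**: per retained factor, peak latency, peak
   loading, per-observation amplitude (score x peak loading) averaged
   over a cluster's electrode rows within participant x condition, and
   electrode-wise topographies of mean peak amplitude.  Cluster
   assignment per factor is an explicit configuration choice (posterior
   centro-parietal vs. anterior fronto-central); the pipeline computes an
   anterior/posterior suggestion from the |amplitude|-weighted topography
   centroid but only writes it to the manifest.

Rows are centered by column (time sample) means and not scaled.  A
cluster-averaged amplitude contrast estimates the injected component
contrast scaled by the component's mean spatial weight over the cluster
electrodes; recovery tests score against that cluster-projected value.

## Factor-wise ANOVA and contrasts

Each retained factor's amplitude table (participant x Constraint x Face,
one cell mean each) is analyzed with the classical two-way
within-subject decomposition: every effect is tested against its own
subject-by-effect interaction stratum, so each F has df = (1, n-1), and
partial eta squared is SS_effect/(SS_effect + SS_error) — equivalently
F/(F + df_error), the identity by which the packaged printed tables are
verified.  With two levels per factor no sphericity correction is needed.
Simple effects (Face within each Constraint level by default) are
participant-wise contrasts of cell means: the estimate is the mean
contrast, the standard error comes from the participant distribution
(df = n-1), and p-values are Bonferroni-multiplied over the requested
family (default 2, configurable).

## Single-trial N400 mixed-model ladder

Single-trial window amplitudes are fit by eight nested linear mixed
models M0..M7 sharing one random structure — correlated
Constraint-by-participant intercepts and slopes plus crossed item
intercepts — and adding sum-coded fixed effects in the order Accent,
Constraint, Face, Accent x Constraint, Constraint x Face, Accent x Face,
and the three-way term.  Sum coding assigns +1 to L2, HC and Face (the
bracketed level in output tables).

All fits maximise the marginal likelihood (ML, never REML) so AICs are
comparable across fixed-effect structures.  The implementation profiles
the fixed effects and residual variance out of the deviance analytically
(penalised least squares on the relative covariance factor) and
optimises only the four relative-covariance parameters with L-BFGS-B
(bounds keeping diagonal entries non-negative; an absolute
finite-difference step of 1e-6 because the deviance scales with n;
Nelder-Mead fallback).  All data products (Z'Z, Z'X, Z'y, ...) are
precomputed, so a deviance evaluation is independent of the trial count
and a study-scale ladder fits in seconds.  The profiled deviance was
verified against a dense GLS evaluation (identical to 1e-8) and against
lme4's bobyqa ML fit (deviance and fixed effects to ~1e-3) on crossed
fixtures.

Reported quantities: -2 logLik(ML) labelled as deviance; AIC = deviance
+ 2k with k counting fixed effects, the four variance/covariance
parameters and the residual; delta-AIC against the minimum; Akaike
weights exp(-dAIC/2) normalized to 1.  Fits with a boundary
(singular) random-effect covariance are retained with a warning flag,
not refit.  Fixed-effect summaries use normal-approximation p-values and
+/-1.96 SE intervals; post hoc Face-within-Constraint contrasts are
linear combinations of fixed effects (2 b_Face +/- 2 b_CxF under +/-1
coding) with z = b/SE and Bonferroni over the two contrasts.  The normal
approximation is anticonservative for much smaller participant counts
than the study's 42; calibration tests therefore run at that scale.

## Synthetic ERP generator

Each component contributes `(base + effect(cell) + u_ik) g_k(t) h_k(e)`:
g_k a unit-peak Gaussian in time (half-Gaussian rise with a plateau for
slow waves), h_k a unit-peak Gaussian over 2D layout distance from a
topography centre, u_ik per-participant amplitude deviations.  Noise is
stationary AR(1) in time, with the coefficient referenced to 250 Hz and
converted per sampling rate; averages carry noise scaled by
1/sqrt(trials per cell).  Single-trial simulation adds item intercepts
through a smooth post-onset step kernel — a constant per-item offset
would be removed by baseline correction, whereas the step delivers the
full offset to the N400 window while leaving the baseline clean — with
items following the design structure (8 x trials-per-cell items, each
seen once per participant, rotated over cells Latin-square style).
Identical seeds give bit-identical data.

Scenario presets: `L1_like` (P2/P3b/N400/slow wave carrying Constraint
and Constraint x Face effects), `L2_like` (N1 and N400 Face effects,
fronto-central P3a), `null` (the same inventory with zero condition
effects, for type-I calibration).  Preset amplitudes are free parameters
of the generator, not estimates from any dataset.  Their single-trial
noise (6 uV, AR 0.35 at 250 Hz) represents already-cleaned epochs:
trial averages must be signal-dominated for the 3% variance filter to
isolate components — the regime real temporal-EFA studies operate in,
where retained solutions explain ~95% of variance.  With strongly
autocorrelated noise (AR 0.9) the correlation-metric Kaiser criterion
retains dozens of noise factors regardless of noise amplitude (the
criterion is scale-free), every component falls below the 3% filter, and
no estimator could recover the design — so the noise defaults are part
of the study conditions the generator defines, stated here once and not
tuned per test.

The recovery preset (`recovery_truth`) uses K equal-strength,
temporally and spatially well-separated components (peaks spread over
100-800 ms, distinct topography centres, spatial spread 0.55) at 12
participants and 20 electrodes; component 2 carries a 1 uV Constraint
contrast for effect-recovery scoring.  A direct mixed-model trial
generator (`simulate_trial_table`) draws single-trial amplitudes from
the ladder's own random-effects structure for model-selection and
calibration experiments; its defaults mirror the study scale with a
residual of 6.2 uV.

What the generator does not emulate: volume conduction/forward head
modelling (topographies are layout-distance kernels), oscillatory and
time-frequency structure, artifacts, latency jitter across trials and
participants, and component correlations beyond what shared participant
deviations induce.  Passing recovery tests therefore show that the
estimators recover structure of this additive-Gaussian kind at realistic
scale; they cannot certify behaviour under latency variability or
non-Gaussian EEG noise.

## Problem sizes used by the test suite

The suite exercises the study design at reduced sizes chosen as the
smallest that leave the tested property identifiable: factor recovery at
12 participants x 20 electrodes x 4 components over 100 seeded runs
(rotation with 2 starts there; the 30-start default is exercised in the
oracle tests), type-I calibration over 500 null-scenario runs at 12
participants, and ladder selection over 100 study-scale (42 x 42 x 8)
simulations.  Geomin's quasi-Newton stage makes the large-m rotations
(the Kaiser criterion retains 60-80 factors at these row counts)
tractable.

## Numerical choices and degenerate inputs

Covariance solves are Cholesky-based with escalating, logged ridge
jitter on singularity.  ULS extraction caps at 500 iterations and raises
with the last off-diagonal discrepancy on non-convergence; Heywood cases
are floored, not rejected.  Rank-deficient correlation matrices in the
Kaiser criterion warn and clip eigenvalues at zero.  Zero error strata
in the ANOVA warn and report F as undefined (0 for null data).  Mixed
models with boundary variance estimates are flagged singular but kept.
Rotation start ties below 1e-8 resolve to the lowest start index;
factor-sign ties (loadings of equal magnitude) resolve to the first
maximal sample.  All randomness flows from explicit seeds; reruns of a
pipeline configuration are byte-identical.

## Known limitations

* The EFA track assumes measurement invariance within an accent;
  condition-dependent component latencies (which motivate separate
  per-accent analyses in the first place) are neither modelled nor
  simulated.
* Variance explained under an oblique rotation has no unique definition;
  the pattern x structure convention here can in principle produce small
  negative shares for strongly correlated factors.
* Normal-approximation p-values for mixed-model fixed effects are
  anticonservative at small participant counts.
* The Kaiser criterion's n is taken as observation rows, which treats
  electrodes and conditions of one participant as independent
  observations; this matches common practice but overstates n.
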