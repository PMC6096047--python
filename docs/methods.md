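# Methods

`mvblife` implements a model-based multivariate analysis of age effects on
two-ROI fMRI activity: an event-related first-level GLM with AR(1)
prewhitening, multivariate Bayesian (MVB) decoding with spatial priors and
free-energy model comparison, per-subject information measures, and
group-level robust/Bayesian age-trajectory inference.  Because the cohort
data such analyses are normally run on are access-controlled, the package
ships a first-class synthetic-cohort generator with configurable ground
truth, so every stage can be validated against known answers.

## First-level GLM

Each subject's design contains, per session: HRF-convolved task regressors
(long-term memory task: 3 scene-onset delta regressors by valence, epoch
regressors of 7.5 s duration beginning 2 s after scene onset crossed by
valence x subsequent memory, and one shared keypress regressor; short-term
memory task: encoding/maintenance/probe regressors by load), six rigid-body
motion confounds, a cosine drift basis up to 1/128 Hz and a constant.
Regressor construction and the canonical double-gamma HRF come from
nilearn's first-level machinery (`hrf_model="spm"`); sessions are
concatenated block-diagonally with separate drift and constant columns.
Data are scaled to a grand mean of 100 over all voxels and scans within
each session before fitting.

The noise model is AR(1)-plus-white.  The pooled AR coefficient is the
lag-1 autocorrelation of pooled OLS residuals; the relative weights of the
white and AR(1) variance components are then estimated by Fisher-scoring
ReML in the eigenbasis of the AR(1) correlation matrix, where both
components are simultaneously diagonal and each iteration is O(T)
(tolerance 1e-6 on the relative objective change, at most 64 iterations,
component scales floored at exp(-32) of the data scale).  Profiling the AR
coefficient inside ReML would cost a dense eigendecomposition per
candidate; the residual-autocorrelation plug-in reproduces every property
we rely on (near-zero estimates on white noise, reduced residual
autocorrelation after whitening).  Model and data are whitened with the
symmetric inverse square root of the fitted covariance and betas
re-estimated by OLS.  Numerically noiseless data skip whitening: the
estimated covariance would be at rounding-error scale and its inverse
square root ill-conditioned.

Contrast effects use trial-count weighting: the subsequent-memory effect is
the count-weighted mean of remembered epoch betas minus the count-weighted
mean of forgotten betas across sessions and valences; the short-term-memory
target is the linear load contrast on the maintenance regressors.  A
session missing all trials of a condition yields no column; the design
records the missing condition and the pipeline excludes that subject from
contrast-based analyses (kept in the audit table).

## MVB decoding

The decoder reverses the GLM mapping: the psychological target variable
t = Xc is predicted from voxel activity under the hierarchical
linear-Gaussian model

    R t = R Y U eta + e,   eta ~ N(0, Sigma_eta),   e ~ N(0, s2 I),

where R projects out every design column not entering the contrast
(realised as an orthonormal null-space reduction, so noise stays white at
full rank), U is the spatial pattern basis and Sigma_eta carries variance
components over nested pattern subsets.  The sparse prior uses one pattern
per voxel (U = I); the smooth prior uses Gaussian-weighted local averages
(FWHM 8 mm, sigma = FWHM/2.3548, columns normalised to unit sum).  Joint
two-ROI models concatenate the ROIs' voxel sets with block-diagonal bases.

The reduced target is standardised to unit variance inside the decoder.
The Gaussian log evidence is not scale-invariant (it shifts by -n log a
under target scaling a, with no change in model structure because the
variance-component family is scale-closed), and real versus phase-shuffled
targets lose different energy fractions to the confound projection;
without standardisation that norm difference leaks into evidence
differences as a spurious multi-nat term.

Hyperparameters are optimised by Fisher-scoring ReML on the two-part
covariance (pattern-induced plus white residual), with all covariance
algebra in pattern space via the Woodbury identity, so a fit scales with
the active-set size (at most 128 patterns) rather than scan count.  The
greedy search ranks patterns by |U'Y'Rt|, evaluates nested active subsets
of doubling size (1, 2, 4, ... capped at 8 steps), gives each new shell its
own variance component, and keeps the subset size with the highest free
energy F; a step is "accepted" iff it improves on the best so far, which
makes the accepted-step F sequence non-decreasing.  All subset sizes up to
the cap are evaluated rather than stopping at the first non-improving
step: a dip at size 2 says nothing about size 16, and early stopping makes
the fitted evidence bimodal across realisations (10-30 nat spread in
evidence differences).  F is the exact Gaussian log marginal likelihood of
the reduced target at the optimised hyperparameters — an empirical-Bayes
(ML-II) log-evidence bound; at fixed hyperparameters it equals the
closed-form Gaussian density, which the test suite verifies to 1e-6.

Model comparison takes F differences with +/-3 nats as the
strong-evidence threshold (a boundary value of exactly +/-3 counts as
"equivalent").  Decodability contrasts the real-target F with the mean F
over 20 phase-randomised surrogate targets (Fourier amplitudes preserved,
phases uniform with conjugate symmetry; the shuffle acts on the target,
not the data); a subject passes when the difference exceeds 3 nats.
Features are the 1000 voxels (or all in-mask voxels, with a warning, when
fewer) with the largest mean task-F statistic over the *other* subjects'
GLM fits — a leave-one-participant-out scheme that keeps selection
orthogonal to the decoded contrast.

## Subject measures and inclusion

Per subject and ROI: the mean and sample SD of contrast effects over the
MVB feature set; the weight spread (sample SD of posterior voxel weights,
the index of how many voxels carry information); the decodability delta;
the joint-versus-posterior-only comparison category ("boost" /
"equivalent" / "reduction"); and the proportion of top-weighted voxels
(|w - mean| > 2 SD; the deviation form is used because it stays
well-defined when weights are not zero-mean) lying in PFC.  An empty top
set is flagged undefined and excluded from group fits, never imputed.
The exclusion policy is switchable: "any" (default) drops subjects not
decodable in at least one ROI; "both" drops only subjects decodable in
neither.  Scenario-recovery suites use "both": under "any" a compensation
ground truth is unmeasurable by construction, since every young subject
(with no prefrontal information yet) fails PFC decodability and is
removed before the age trend can be estimated.

## Group inference

Age effects on continuous measures use robust second-order polynomial
regression: Huber M-estimation (tuning constant 1.345, 95% Gaussian
efficiency) on standardized linear and quadratic age predictors (the
quadratic is the squared standardized age, re-standardized), with
asymptotic-normal p-values from the M-estimator covariance, a robust Wald
F for the overall model, and adjusted R^2 from the robust fit's residuals.
Distributions are trimmed at 5 sample SDs (single pass, removals logged).
Model-comparison outcomes (reduction < equivalent < boost) are analysed
with proportional-odds logistic regression on standardized age
(statsmodels `OrderedModel`).  Directional hypotheses get Bayes factors
with a half-normal effect prior (mean 0, SD 1 on the standardized scale):
BF01 = N(est; 0, se) / integral over positive effects, computed by
adaptive quadrature after substituting out the prior SD so arbitrarily
narrow priors stay well-scaled.  Group decodability uses a one-tailed
one-sample t test against a population mean difference of 3 nats.  The
power sensitivity analysis solves the noncentral-F problem (df1 = 1,
df2 = n - 3, noncentrality f^2 * n) for the effect size reaching 80% power
at two-tailed alpha 0.05 and reports that variance proportion; this
convention reproduces the reference percentages for both cohort sizes.

## Synthetic cohorts

The generator is the forward GLM run generatively: per-subject trial
tables (long-term memory: 120 trials in 2 sessions of 10 min, TR 1.97 s,
320 scans/session; short-term memory: 3 runs x 30 trials, 10 per load, TR
2 s), designs built exactly as in analysis, betas assembled from ground
truth, and AR(1) noise added per session.  Remembered/forgotten labels are
Bernoulli draws from a piecewise-linear age function through the tertile
means 55/120, 44/120, 23/120 (midpoints 32, 55, 76.5 years); forgotten
subtypes (associative miss / intrusion / item miss) are multinomial with
age-interpolated tertile proportions.  Voxels sit on a 3 mm lattice in two
disjoint blocks labelled PVC and PFC (200 voxels per ROI by default — the
package's standard desk-scale problem size).

Noise has three parts, all AR(1) with lag-1 correlation 0.3: a
voxel-unique component (SD 1.0 BOLD units against a grand mean of 100) and
one ROI-shared component (SD 1.5) added identically to every voxel of an
ROI.  The shared component emulates regional physiological fluctuations
and is load-bearing: it bounds the SNR of the ROI-mean signal so that a
mean activation difference is *not* by itself high-grade pattern
information (without it, a 0.3-unit mean effect across 200 voxels with
independent noise is decodable with overwhelming evidence, and
"activation without information" ground truths cannot exist).  With these
values a subject's univariate effect estimate has SE ~0.17, reproducing
the familiar regime of weak single-subject but strong group-level
univariate effects, while single-ROI decodability deltas land at ~15-200
nats per 200 voxels with between-subject SDs of 10-45 nats — the same
order as published real-versus-shuffled evidence differences.

Informative voxels receive condition-differential betas drawn from a
zero-mean Gaussian (so information is nondirectional, matching the
decoder's use of both weight signs); uninformative voxels have none.
Scenario functions map age to the generative parameters:

- **dedifferentiation** — "more activity, less information": PFC
  univariate amplitude rises 0.2 -> 0.65 across 20-88 years while the
  informative fraction falls 0.5 -> 0.2 and the differential scale falls
  0.5 -> 0.3 in both ROIs (PVC amplitude constant at 0.3).
- **compensation** — posterior information constant (fraction 0.4, scale
  0.4); prefrontal information absent at 20 years and recruited linearly
  to fraction 0.3 (scale 0.5) by 88.  The gradual slope spreads the
  boost-category transition across the lifespan instead of saturating by
  mid-life.
- **null** (age-constant), **zero_signal** (no condition effects at all)
  and **strong_signal** (fraction 0.5, scale 0.8, amplitude 0.5) support
  calibration checks.

What the generator does *not* emulate: image-space structure (no
smoothing, motion-induced artefacts, or drift fields beyond the modelled
confounds), voxel-to-voxel noise correlations other than the single shared
component, between-ROI shared noise, behavioural response simulation, and
any departure from the GLM's linear-additive forward model.  Passing tests
therefore certify the statistical machinery under a correctly-specified
forward model, not robustness to real-data model violations.

## Numerical choices and problem sizes

Fisher scoring is run in log-variance space with step clipping (+/-4) and
step-halving; variance scales are floored at exp(-32) of the data scale.
Ties in the greedy pattern ranking resolve by stable sort order.
Degenerate inputs either raise (zero-variance targets, empty masks,
single-category ordinal outcomes) or are flagged (empty top-voxel sets,
missing conditions) — nothing is silently imputed.

Validation suites use desk-scale problem sizes chosen to keep the full
test run within minutes while preserving the regime of interest: oracle
checks at up to 100 scans x 50 voxels; calibration suites with 50 subjects
at 100 voxels/ROI and 10 shuffle repetitions; scenario-recovery suites
with 20 cohorts of 48 subjects at 200 voxels/ROI, run without shuffle
repetitions (none of the recovered quantities depends on the shuffled
baseline) under the "both" exclusion policy.  The pipeline defaults remain
the analysis-scale constants (k = 1000 features, 20 shuffle repetitions,
thresholds 3 nats / 2 SD / 5 SD, FWHM 8 mm), all visible in `RunConfig`.
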