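# Methods

`dpcsig` analyzes trial-structured fMRI parcel time series from a two-condition
emotion-regulation task: on each trial a participant recalls a negative
autobiographical memory and either imagines a supportive conversation with a
peer (*imagined support*) or dwells on their own feelings (*self-feel*).  The
package finds a single spatio-temporal axis that separates the conditions,
decodes condition from held-out trials, identifies which parcels carry the
separation reliably, and links per-trial expression of the axis to negativity
ratings and trait measures.  Because the pipeline is validated against
simulation, the synthetic generator is a first-class component with explicit
ground truth.

## The demixed-PCA signature model

Each trial is a matrix `X` of shape parcels x timepoints (214 x 20 at the
default geometry, TR = 1 s) in cleaned z-score units.  Trials are averaged
within condition, each parcel's grand mean (equal condition weighting) is
removed, and the trial-averaged tensor is split additively into

* a **condition-independent part** `X_time` — the time course shared by both
  conditions, and
* a **condition-dependent part** `X_cond` — the remainder, antisymmetric
  across the two conditions.

Conditions are weighted equally in this marginalization so the design's 56/44
trial imbalance cannot contaminate the condition axis (count weighting is
available via `weighting="count"`).

A single decoder/encoder pair `(d, f)` for the condition part solves the
regularized reduced-rank regression

    min_{d, f} || X_cond − f dᵀ X ||²_F  +  ridge(λ),

computed as the ridge solution `B = X_cond Xᵀ (X Xᵀ + λI)⁻¹` projected onto
the top left-singular direction of its fitted values `B X`; `d` is normalized
to unit length and the scale absorbed into `f`.  A single rank-1 component is
fit because the per-trial feature vector is defined as the projection of that
one axis over time (20 features per trial); the variance fractions of both
marginalizations are recorded in `variance_explained`.

**Ridge default.** λ defaults to `1e-3` times the leading eigenvalue of the
data Gram matrix.  With fewer condition x time cells than parcels the
unregularized readout interpolates condition-mean noise — the decoder whitens
against low-variance noise directions and tilts far from the underlying
spatial pattern even when the encoder recovers it almost perfectly.  Pinning
the ridge to the leading Gram eigenvalue (a standard relative-regularization
convention for ill-conditioned inverses) suppresses those directions while
leaving the dominant condition axis essentially unbiased.  `lam=0` recovers
the raw reduced-rank solution, which on small full-rank problems agrees with
a brute-force generalized-eigenvalue oracle to 1e-8 (tested).

**Sign convention.** dPCA axes are sign-ambiguous.  After fitting, `d` is
flipped if necessary so that the time-averaged projection of imagined-support
training trials exceeds that of self-feel trials (`support_positive`).  The
rule is deterministic and idempotent; exact ties keep the current sign and
emit a warning.

**Projection.** A trial's dPC expression time course is
`z(t) = dᵀ (x(:,t) − grand_mean)`; single trials are never refit, only
projected, which is standard demixed-PCA practice.

## Decoding

A logistic model classifies imagined support vs. self-feel from either the
20-point dPC time course (`dpc` mode) or the 214 per-parcel time means
(`mean_activity` baseline mode).  The evaluation engine draws `B` train/test
splits (default 90/10, grouped by participant so accuracy measures
generalization to new people; trial-wise splitting is available).  Inside each
replicate the dPCA fit, its sign orientation, feature standardization, and the
classifier are computed from training trials only — nothing downstream of the
split ever sees a held-out trial, and a dedicated test plants signal only in
held-out trials to confirm chance-level accuracy.

Class imbalance is handled with a uniform prior, implemented as
inverse-frequency class weights in the logistic loss.  Reported "accuracy" is
balanced accuracy (the mean of sensitivity and specificity) so that chance is
0.5 at any prevalence; sensitivity, specificity, AUC and the F2 score
(F-beta with beta = 2, imagined support positive) are recorded per replicate.

Significance uses a label-permutation null: condition labels are permuted at
the trial level and the entire B-replicate procedure is re-run on the same
splits, giving `p = (1 + #{null ≥ observed}) / (n_permutations + 1)`.  Paired
model comparisons (e.g., dPC vs. mean-activity) use a sign-flip test over the
shared per-replicate accuracy differences.

## Parcel reliability

Participants are resampled with replacement `B` times; the oriented decoder is
refit on each resample and its unit-norm parcel loadings recorded.  Each
parcel's mean/SD ratio across replicates is referred to a Student t
distribution with `B − 1` degrees of freedom, two-sided against zero — the
parametric-bootstrap reading that permits p-values far below `1/(B+1)`.  The
t reference (rather than normal) matters at small `B`: it accounts for the
estimated SD and keeps the complete-null family-wise behavior of BH at its
nominal level (tested at B = 60); at B = 1000 it is indistinguishable from
the normal.  Benjamini–Hochberg is applied across all parcels as one
two-sided family, and positive loadings map to imagined support.  An
alternative scoring via balanced-logistic coefficients on mean activity is
available (`loading="logistic"`).

## dPC similarity and behavioral linking

**dPC similarity** of a trial is the Pearson correlation between its dPC time
course and the mean dPC time course of all imagined-support trials.  The
reference includes the indexed trial by default; a leave-one-out variant
removes the (small, positive) self-similarity bias of support trials.

* **Trial level**: similarity ~ outcome group with a participant random
  intercept (linear mixed model, REML).  A trial is *less negative* when its
  post-trial negativity rating falls below the memory's pre-scan baseline
  rating (a cohort-median split is available).  The t reference uses a
  containment-style df, `n_obs − n_participants − 1`; statsmodels does not
  provide a Satterthwaite approximation, and at these group counts the two
  differ negligibly.
* **Individual level**: trait ~ mean similarity over imagined-support trials
  + wave + age, by OLS, for loneliness (ULS-8 item mean), life satisfaction
  (SWLS sum) and support nominations (0–6).  Constant covariates are dropped
  with a warning; rank-deficient designs raise an error naming the collinear
  columns.
* **Behavioral contrast**: Welch two-sample t-test on negativity ratings,
  imagined support minus self-feel.

BH-FDR is applied within each declared family (the trial-level scopes
together; the three trait models together) via `adjust_family`.

## Time-series extraction

The cleaning chain is fixed and ordered: confound regression (least squares
with intercept) → linear detrend → zero-phase order-5 Butterworth band-pass
(0.01–0.12 Hz) → per-parcel voxel mean → per-parcel z-score.  Averaging last
preserves within-parcel voxel weighting; z-scoring last makes "standardized"
the output's final state.  Label 0 is background; output columns are sorted by
label value, and zero-variance parcels are zeroed and flagged rather than
propagating NaNs.  Epochs start at the volume nearest the event onset
(`round(onset / TR)`, 0-based) and span exactly `n_timepoints` volumes; longer
event durations are truncated, matching a design in which only the first 20 s
of a 30 s memory phase is analyzed.

Numerical caveat: the projection steps (confound regression, detrend,
z-score) are exactly idempotent when the confounds carry no trend component,
but zero-phase IIR filtering of a finite window is not a projection.
Re-cleaning already-cleaned data reproduces it only approximately (finite-
window transients of a few percent RMS for in-band signals, ~2% amplitude
shift per pass for components near the 0.12 Hz corner).  The tests assert
exact idempotence for the projection steps and a 5% relative-RMS bound for
the full chain.

## The synthetic generator

`generate_dataset` emulates the study design: 95 participants (48/47 across
two recruitment waves), 12 trials each, Bernoulli(0.56) imagined-support
assignment, 214 parcels x 20 timepoints at TR = 1 s.  Each trial matrix is

    baseline_i  +  a·√P · v h(t)ᵀ  +  s_c · snr · √P · gain_it · w g(t)ᵀ  +  ε,

with `w` a unit-norm spatial pattern supported on 20 parcels, `g(t)` an
evoked-response-like bump (gamma kernel, RMS 1), `s_c = +1` for imagined
support and `−1` for self-feel, `gain_it = 1 + a_i + η_it` carrying
participant (SD 0.3) and trial (SD 0.25) variability, a participant-specific
spatial baseline (SD 0.5), a condition-independent evoked response shared by
all trials (amplitude 0.5), and AR(1)-in-time (coefficient 0.3), white-in-
space noise of unit variance.  The √P factor makes `snr` the ratio of
planted-signal SD to noise SD over matrix entries; the default `snr = 1` is
the recovery condition the validation suite is specified at.

**True expression.** The generator defines a trial's true signature
expression as the Pearson correlation between the planted-axis projection
`wᵀX` of the generated (noisy) trial and `g(t)` — the ground-truth analogue
of the pipeline's dPC similarity.  The noiseless projection correlates with
`g` at exactly ±1, so coupling behavior to the realized similarity is the
only definition under which downstream regressions are well specified and
planted slopes are recoverable quantities.

**Ratings** are a latent-Gaussian construction: baseline negativity (an
integer 2–5 drawn with mode 4, as memories are selected to be negative) plus
a participant intercept (SD 0.3) minus `rating_slope` x expression plus
N(0, 0.8) noise, rounded and clipped to the 1–5 response scale.  The default
slope 0.5 makes imagined-support trials ~half a rating point less negative,
the size of the cohort's behavioral contrast.

**Traits** are linear in the participant's mean expression over
imagined-support trials, plus a wave offset (0.2) and instrument noise:
loneliness on the ULS-8 item-mean scale (base 2.2, noise SD 0.45), SWLS sum
(base 23, SD 6), and support nominations generated around mean 3.86 / SD ~1.8
and clipped to 0–6 integers.  Default slopes (−0.22, 0.27, 0.58) mirror the
sign/magnitude pattern of the cohort effects.  With the default `snr = 1`,
per-trial similarity saturates near ±1, so between-participant regressor
variance is small and trait slopes are estimated with wide intervals; the
slope-recovery simulations therefore use a scaled condition (snr 0.6,
between-participant gain SD 0.8) in which the estimate is unbiased and
informative.  This is a property of correlation-valued signatures, not of
the estimators.

`generate_voxel_session` lays one participant's trials into a single run at
voxel resolution (parcels broadcast to voxels, optional voxel noise), injects
global-signal and drift nuisance series that are recorded in a BIDS-style
confound table, and writes 20 s events — so the extraction front-end can be
tested as an exact round trip.

**What the generator does not emulate:** hemodynamic convolution, head
motion, multi-run sessions, spatial autocorrelation between parcels, and
condition-correlated artifacts.  Passing tests therefore demonstrate the
estimators' statistical correctness under the stated noise model, not
robustness to every property of real BOLD data.

## Problem sizes and determinism

Monte-Carlo validation scales sizes, not logic: single-dataset checks run at
the full 95 x 12 x 214 x 20 geometry; repeated-simulation checks (null
calibration, slope coverage) use 12–40 participants, 24–50 parcels and B of
8–60 so that hundreds of replications complete in minutes.  Every stochastic
routine takes an explicit seed, splits are drawn before any fitting so paired
comparisons share resamples, and all writers are byte-deterministic (no
timestamps, sorted JSON keys), which the CLI-replay tests assert file by
file.

## Known limitations

* The mixed model reports a containment-df t rather than Satterthwaite.
* Permutation p-values are discrete (resolution `1/(n_permutations+1)`).
* The reference time course is in-sample by default (see leave-one-out flag).
* BH control under the decoder's cross-parcel dependence is verified
  empirically under the complete null, not proved.
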