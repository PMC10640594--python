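# Methods

This note documents the models, estimators and numerical choices behind
`graftdyn`, and what the synthetic benchmark does and does not establish
about real recordings.

## Preprocessing

Continuous denoised traces and their denoising residuals (both cells ×
time at 10 Hz) arrive with a behavioral event table.  Trials are cut
around an alignment event over a half-open window `[-pre, +post)`; trials
whose window leaves the recording are dropped and logged.

**Baseline correction** divides each cell/trial trace by the noise scale
`b` of its pre-movement residual: the population SD (ddof = 0) of the
residual samples in the −5…−4 s window before pellet touch, *averaged
across trials* so each cell has one divisor.  A per-trial variant
(`trial_pooled=False`) exists, but a 1 s window holds only ten samples at
10 Hz, so per-trial divisors carry ~25 % estimation noise; dividing by
them injects multiplicative cell×trial noise that measurably depresses
any downstream covariance statistic (factor-analysis shared variance
drops by ≈ 0.045 in controlled recovery experiments).  The averaged
reading removes this while preserving the per-cell amplitude
normalization the correction exists for.

**Binning** averages non-overlapping 0.5 s bins (5 samples at 10 Hz),
labeled by their left edge.  The per-trial mean over the binned window is
preserved exactly.

## Task and cue modulation

Per cell, a one-way ANOVA across time bins with trials as replicates is
followed by Tukey's HSD over all bin pairs; the cell is *modulated* when
any pair is significant at α.  The Tukey criterion is evaluated against
the studentized-range critical value `q_crit(α, k, k(n−1))`, which is
exactly the "any pairwise p < α" rule but vectorizes over thousands of
cells; the omnibus F p-value is reported as metadata, and the family-wise
construction keeps the per-cell false-positive rate at α (measured 0.052
on 1000 null cells).  Cells with zero within-bin variance are excluded as
non-computable.

The task test uses 0.5 s bins over −2.5…+2.5 s from pellet touch
(10 bins) and the cue test −1…+1 s from the door-open tone (4 bins).  A
cue-significant cell is *cue-preferential* when its trial-averaged
activity peaks before reach onset (a manual annotation; when absent, the
pellet touch is the default boundary, and analyses that know the true
reach time should pass `reach_onset_s` explicitly).

**Behavior correlation.**  The success rate is regressed on the
proportion of task-modulated cells with a linear mixed-effects model
(random intercept and random slope per mouse, REML).  Both variables are
z-scored first, so the fixed-effect slope lies on the correlation scale
and is reported as `r`; this is the only reading under which a mixed-model
slope is interpretable as a correlation coefficient.  A singular
random-slope fit falls back to random-intercept-only; a single mouse
degenerates to OLS with a warning.

## Population metrics

**Co-firing** binarizes each cell at mean + k·SD (k = 1 by default; the
raster is invariant to affine rescaling of a trace) and counts coincident
supra-threshold samples as the dot product of binary vectors.

**Factor analysis and SOT.**  Task-window samples are pooled across
trials (observations = trial × time points, variables = cells) — the only
sample space in which "two shared factors explain most of the activity"
is a well-posed statement.  Maximum-likelihood factor analysis
(deterministic SVD-based fit, tolerance 1e-6, max 1000 iterations;
non-convergence is an error, Heywood uniquenesses are floored at 1e-6
with a warning) yields loadings `L` and uniquenesses `ψ`, and

    SOT = Σ‖L_c‖² / (Σ‖L_c‖² + Σψ_c).

The factor count q = 2 follows the principal-component spectrum of task
activity; `pca_loo` cross-validates that choice by projecting each
held-out trial onto components fit without it.  Its explained-variance
ratio is energy-weighted across folds (total captured energy over total
held-out energy) rather than a mean of per-trial ratios, which is biased
when trials differ in amplitude.

**Trajectories** are posterior-mean factor scores of the trial-averaged
activity smoothed with a Gaussian kernel (default length scale 0.3 s) —
the high-signal-to-noise limit of a Gaussian-process factor model, kept
deterministic on purpose.

## Longitudinal tracking

Consecutive session maps are matched by Hungarian assignment on centroid
distance, gated at `max_dist_px` (default 8 px) and, when footprints
exist, at footprint correlation ≥ 0.6; identities chain transitively.
The spatial gate alone admits chance matches at realistic cell densities
(~0.002 cells/px²); the footprint gate removes most of them, which is why
the pipeline generates footprints by default.  Task covariance between
tracked cells is Pearson correlation of trial-concatenated task-window
activity, tested two-sided against a trial-permutation null (permuting
one cell's trial order preserves within-trial structure and breaks only
the trial-by-trial co-variation being tested; a circular shift would test
a different null).

## Stimulation analysis

Sessions are three 300 s blocks (baseline / stimulation / post) at 10 Hz
with 20 onsets at 15 s spacing.  Two modulation tests: (i) the ANOVA
machinery on onset-aligned 1 s bins from −5 s to +10 s around onset;
(ii) the trial-averaged 95th-percentile ON-window amplitude against the
95th percentile of 1000 circular-shift surrogates (shifts preserve the
trace's autocorrelation and amplitude distribution).  Both calibrate to
≈ 5 % on null sessions.  A cell is *responsive* when either test flags it.

**Deconvolution** inverts the AR(1) calcium model exactly
(`s_t = y_t − γ·y_{t−1}`, `γ = exp(−1/(rate·decay))`, decay 0.5 s),
rectifies, and takes local maxima above 3× the MAD-estimated noise SD of
the *unrectified* innovation signal (rectification zeroes half the
samples and would halve the MAD).  For isolated transients the innovation
at the event equals the transient amplitude, so amplitudes are recovered
directly.  A 3σ threshold admits occasional tail crossings (~0.1 % of
frames); event-ratio statistics are robust to these, exact event counts
on noisy traces are not.

**Event-ratio classes.**  Per cell, block counts are normalized by the
cell's total 15 min count; a block is `increased`/`decreased` versus
baseline when its ratio differs by more than 0.10 absolute (a
relative-change option exists), `no_change` otherwise, `inactive` with no
events.  The reference block and the absolute reading are configurable
because both conventions appear in practice.

## Blood flow

The vessel mask is a global threshold (Otsu by default, manual override)
of the box-smoothed maximum projection, with small objects removed; an
empty or fragmented result raises rather than returning garbage.
Cell-to-vessel distances are exact Euclidean distances to the nearest
mask pixel (KD-tree), summarized by linear-interpolation percentiles.

Speed estimation tiles the mask with boxes of side 8.8 µm (stride = side).
Within a box, each pixel's mean-subtracted 30 s segment is
cross-correlated with every neighbor; the lag is the centroid of the
correlogram's contiguous > half-max support after 16× band-limited (FFT)
upsampling — plain integer-grid centroids carry ±0.05-frame bias, fatal
when lags at 1–2 mm/s are 0.1–0.3 frames.  Pair separation is projected
onto the local flow axis (first principal axis of the box's vessel
pixels): the lag reflects axial displacement only, so Euclidean
separations overestimate speed by up to √2 on diagonal pairs (the
Euclidean option remains available).  A reference pixel's speed is the
ratio of summed separations to summed |lags| — a distance-weighted mean
that avoids the upward Jensen bias of averaging 1/lag — the box speed is
the maximum over its pixels, and both per-pixel samples and box maxima
are reported.  Pairs with |lag| below 0.02 frames are skipped; a box with
no valid pair (e.g. a static pattern) is excluded and counted.  Searched
lags span ±0.5 s.  Validation on synthetic videos: medians within ±4 %
at 0.5, 1 and 2 mm/s, regression slope 1.02.

## Synthetic data: what it emulates and what it does not

`gen_task_session` builds, per trial, (i) trial-locked transients
(instantaneous rise, 0.5 s exponential decay) for modulated cells at
latencies drawn with a configurable spread — giving the sequential
activation seen when sorting cells by latency; (ii) zero-mean shared
factor fluctuations on q = 2 latent time courses; (iii) per-cell×trial
amplitude jitter; (iv) white Gaussian private noise, plus an independent
white residual channel standing in for the denoiser's residual output.

Two structural choices matter.  First, the transient family across
latencies is compressed onto its top-q principal time courses, and each
cell's response is the rank-q projection of its ideal waveform (visually
indistinguishable; latency spread 0.4 s vs 0.5 s decay).  Second, the
factor fluctuations are per-trial gains on those same transient
coefficient patterns (`factor_scope="modulated"`), so the noiseless
shared covariance is *exactly* rank q and the target shared fraction can
be calibrated numerically (Brent search on the top-q eigenvalue fraction
of the realized covariance, with amplitude-jitter variance counted as
private since it is uncorrelated across cells).  With
`factor_scope="all"` (the default contract: every cell loads on the
factors) unmodulated cells gain random-direction loadings; the shared
covariance is then rank ≈ 2q and a q-factor analysis under-reports SOT by
roughly 0.03–0.04 at low modulated fractions — a property of the
estimator, not a bug; the session-phase simulations therefore use the
rank-exact scope, which also matches the interpretation that task-related
co-firing carries the shared variance.  Cue cells keep their ideal
waveforms at the door-open latency (outside the task-factor basis).

The ACS generator lays Poisson background events (0.05 Hz), ON-locked
transients for responsive cells, and a rate reduction (×0.2) in the post
block for suppressed cells, convolved with the same AR(1) kernel the
deconvolution inverts, at amplitude ≈ 6.7× the trace noise — denoised
transients in this preparation sit well above residual noise, and a
generator that placed events at the detector's threshold would test the
tie-break, not the method.

The flow generator advects anisotropic intensity trains (axial σ 20 µm,
transverse σ 2 µm) along the vessel with 4-substep motion blur, drawing a
fresh transverse offset and brightness when a particle re-enters (keeping
the texture aperiodic, as newly arriving cells would).  The 20 µm
correlation length keeps passage times near the 16.7 ms frame period over
0.5–2 mm/s; much shorter textures alias at 60 Hz and bias any
correlogram-based lag toward zero.  Cell positions are placed by matching
a target distance (uniform over 0–76.2 µm by default) against the
distance transform, with the exact realized distance stored as truth.

Not emulated: photobleaching, motion artifacts, stimulation artifacts,
dye leakage, non-Gaussian noise, overlapping cells, slow drifts in
baseline or cell health, and any pixel-level calcium movie for the trace
pipeline (traces are generated directly).  Passing tests therefore
establish that the estimators are correct and calibrated under the
generative assumptions above — not that those assumptions exhaust real
miniscope data.

## Problem sizes and determinism

Default benchmark sizes: 50–60 cells × 40 trials per session (≈ 6000
pooled task samples), 1000 null cells for calibration, 300-cell base
population over 3 sessions for tracking, 60-cell / 900 s ACS sessions
with 500 surrogates, 80 × 400 µm / 30 s / 60 Hz flow videos, 258 cells
for distance summaries; phase-level quantities average three simulated
animals.  All randomness flows from explicit integer seeds through
`numpy` generators (the pipeline derives stage seeds from one root seed
via `SeedSequence`), factor analysis uses a deterministic initialization,
and all writers use fixed float formats, so a rerun with the same
configuration is byte-identical.

## Known limitations

* The ANOVA treats bins within a trial as independent; shared-factor
  fluctuations make them mildly dependent, measured as a ~2 % absolute
  excess in the false-positive rate on factor-loaded (not pure-noise)
  null cells.
* The 95th-percentile amplitude null uses whole-trace circular shifts;
  strongly non-stationary backgrounds would need block-wise surrogates.
* The LME's random-slope variance is often estimated at zero for small
  cohorts (it then silently reduces to random-intercept).
* Speed estimation assumes a locally straight vessel within each 8.8 µm
  box and reports magnitudes only; branching geometries and reversing
  flows are out of scope.
* Registration without footprints over-matches at high cell density;
  provide footprints or tighten `max_dist_px`.
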