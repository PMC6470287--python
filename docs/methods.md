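# Methods

This note documents the models, algorithms, parameter choices and
limitations of `bsfc` in the order the pipeline runs.

## Suppression detection

The detector computes a per-channel moving-RMS amplitude envelope
(window 0.25 s), normalizes each channel's envelope by its own 90th
percentile — a robust estimate of burst-level amplitude that makes detection
invariant to per-channel gain and to global rescaling — sums the normalized
envelopes across channels, and marks samples suppressed where the sum falls
below a threshold fraction (default 0.25) of the summed envelope's own 90th
percentile.  Suppression runs shorter than 0.5 s are discarded and burst
gaps shorter than 0.2 s merged, reflecting the physiological scale of
burst-suppression cycling.

Centered moving-RMS thresholding has a known systematic edge bias: for an
amplitude step, the envelope crosses `f · A_burst` a distance
`w · (1/2 − f²)` *inside* the suppression (w = window, f = threshold
fraction), shrinking every interval at both ends.  The detector removes this
closed-form bias, which brings single-interval boundary errors below 0.05 s
and the temporal Jaccard overlap with ground truth above 0.95 at a 20:1
burst:suppression amplitude ratio.  The thresholds themselves are declared
package defaults (the procedure they implement is typically finished by
visual inspection in practice and no canonical values exist); they are
deterministic and exposed in `DetectionParams`.

A flat (zero-variance) recording raises a detection error rather than
returning an empty result, since "no suppressions" and "no amplitude
contrast" are different findings.

## BS regressor

The binary pattern (0 = suppression, 1 = burst) is convolved at its native
sample rate with the canonical double-gamma HRF — gamma-density peak
(delay 6 s, dispersion 1 s) minus undershoot (delay 16 s, dispersion 1 s)
divided by 6, kernel 32 s, unit peak — then sampled at volume onsets
`t = k · TR` and mean-centered.  Convolving at the EEG rate rather than the
TR grid preserves sub-TR timing of suppression onsets.  The first 10 volumes
of each run are treated as discarded dummy scans, so the regressor aligns
with the retained volumes.

## Preprocessing

Parcel-level only: voxel-to-parcel averaging is assumed done upstream (the
synthetic generator produces parcel series directly).  Stages: per-parcel
linear detrend; OLS nuisance regression (intercept, six motion parameters,
white-matter and CSF signals, optionally the BS regressor); zero-phase
4th-order Butterworth band-pass 0.01–0.1 Hz (applied forward-backward, so
no phase lag distorts connectivity; the filter type/order is a package
choice — only the band is canonical).  The band-pass output is re-centered
to exactly zero mean because DC lies outside the passband by definition and
edge transients otherwise leak a small constant.

The stage order is configurable because it matters: regression before
filtering removes the nuisance component exactly (it lies in the design
span), whereas filtering first leaves a mismatch between filtered data and
unfiltered regressors; the package's tests verify the resulting inequality
in residual nuisance correlation run-by-run.  Regression is per-run OLS;
subject effects enter only at group level.

## Coupling statistics

Per run, each parcel is regressed on [intercept, BS regressor]; the slope is
the coupling beta.  Group inference models per-parcel betas on [intercept,
subject indicators] (one reference subject) and tests the intercept,
Bonferroni-corrected across parcels — the parcel-level stand-in for
voxelwise FWE, which is out of scope here.  Degenerate designs (an SW run's
zero-variance regressor, collinear nuisance columns) raise named errors; an
exactly-fit response (zero residual variance at rounding level) yields t = 0
rather than a ratio of rounding noise.

## Whole-brain statistics

FC is the Pearson correlation of preprocessed parcel series.  Edgewise
group comparison runs on Fisher-z values (variance stabilization; the
transform choice is a package decision) with design [intercept, group,
subject indicators]; Hedges' g (`J = 1 − 3/(4(n₁+n₂) − 9)`) is computed on
the raw correlation scale, matching a plain two-group effect size.

NBS correction thresholds edges at two-sided p < 0.001 on |t|, extracts
connected components, and scores them by extent (edge count; the intensity
variant is not implemented).  The null distribution of the maximal component
size comes from permutations of the group labels *within subject strata* —
the covariate-respecting exchangeability scheme: permuting across subjects
would break the subject effects the model adjusts for.  Component p-values
use the (1 + exceedances)/(1 + permutations) convention.  Edges in
components below the cluster threshold (default 0.05) are flagged and
signed by the group coefficient.

The lobe-block analysis counts flagged edges per unordered lobe pair
(including within-lobe blocks), compares with the expectation
`E = D · m_b / M` under uniform placement of the D flagged edges among the
M possible edges, and standardizes as `Z = (O − E)/√E` (raw residuals sum
to zero by construction).  Its permutation null re-places the D edges
uniformly without replacement; the p-value is the literal exceedance
fraction `#{Z_perm ≥ Z_obs}/n_perm` (no +1 — matching the stated definition
of this particular test, unlike the NBS convention above), Bonferroni
corrected over blocks.  With default n_perm = 5000 the Monte-Carlo error is
≈ 0.007, comfortably inside the ±0.02 agreement the tests require against
exact enumeration on the 6-node case.  A degenerate block with no possible
edges reports Z = 0.

The packaged 94-region partition (82 cortical Regional-Map-style labels +
12 subcortical, nine lobes) is a constructed, synthetic stand-in — the
canonical grouping is not redistributable — and is fully user-replaceable
via any table with `region` and `lobe` columns.

## Seed-based analysis

The seed regressor is the mean preprocessed series over the seed regions
(bilateral PCC for the default-mode network; bilateral thalamus for
thalamocortical connectivity); targets are all non-seed parcels and the
connectivity strength is the OLS beta.  Within-group inference is the same
covariate-adjusted one-sample model as coupling; the between-group test is
the two-group linear model with subject indicators — with two groups a
repeated-measures ANOVA collapses to exactly this model, so one code path
serves both, and Bonferroni across targets replaces voxelwise FWE.

## Physiology summaries

Group means and BS-vs-SW tests per subject for BSR, heart rate, EtCO2 and
temperature, computed from the packaged per-run table.  The test is the
pooled-variance two-sample Student t: the choice is an inference — the
source table does not name its test — adopted because it reproduces every
printed p-value (0.125, 0.120, 0.421, 0.064) from the printed per-run data.
Display rounding is decimal half-away-from-zero (banker's rounding would
print 15.865 as 15.86, not the published 15.87), and p < 0.0005 renders as
"<0.000" to match the published convention.

## Synthetic data

The generator defines the conditions under which the pipeline is validated.

- **Burst/suppression process**: alternating renewal process starting in
  burst; epoch durations exponential by default (memoryless alternation;
  gamma(k = 4) available for more regular cycling).  Duration statistics are
  not constrained by published values; the default mean cycle of 12 s with
  the suppression share set by the target BSR is a plausible scale for deep
  isoflurane anesthesia.  Over a 400 s run the renewal variability of the
  achieved suppression fraction is several BSR points, so the cohort
  generator redraws the process (seeded, at most 100 attempts) until the
  achieved BSR is within 5 points of the run's target; the achieved value is
  recorded as ground truth.
- **EEG**: two-regime amplitude model — band-limited (1–30 Hz) oscillation
  at 50 uV RMS during bursts, white noise at 2.5 uV during suppression
  (20:1), plus 0.5 uV channel noise; 21 channels at 500 Hz by default
  (a desk-scale stand-in for 5 kHz acquisition; configurable).  No MR
  gradient or cardioballistic artifacts are simulated, so detection results
  here bound what artifact-contaminated real EEG would give.
- **BOLD**: 94 parcels × 200 volumes at TR 2 s (400 s, matching the
  acquisition design; 10 dummy volumes).  Signal = per-parcel coupling beta
  × unit-variance BS regressor (betas drawn once per cohort, N(1, 0.3) in
  noise-SD units) + latent unit-variance network factors with block
  loadings (defaults: DMN-like block at loading 0.6, +0.25 in BS runs;
  thalamocortical 0.3, +0.35; OFC 0.4, +0.3 — signs chosen so BS runs show
  the increased within/between-block connectivity the group statistics
  should detect) + eight AR(1) nuisance series (lag-1 coefficient 0.9,
  mimicking slow drift) mixed with fixed N(0,1) per-parcel weights at gain
  0.5 + unit white noise.  Loading-implied edge covariance differences are
  recorded as ground truth, so expected FC values have a closed form
  (`r = l₁l₂/√((l₁²+σ²)(l₂²+σ²))` for block-mates).
- **Cohort**: 27 BS + 11 SW runs from two subjects (20 + 8 and 7 + 3),
  with per-run target BSRs taken from the packaged physiology table;
  per-run RNG streams are spawned from the master seed, so cohorts are
  byte-reproducible.

What the generator does *not* emulate — hemodynamic nonlinearity, spatially
structured noise, motion spikes, field inhomogeneity, EEG artifacts —
bounds what passing tests show about real data: they validate the
statistical machinery and its calibration, not robustness to acquisition
artifacts.

## Problem sizes in the validation suite

Recovery and calibration checks run at sizes chosen to make their
statistical targets meaningful on a single CPU: detection on full-scale
400 s / 500 Hz / 21-channel EEG; coupling recovery on a 20-run, 94-parcel
cohort; FC inflation on 10 BS runs; NBS family-wise error on 200 null
cohorts of 30 parcels and 20 runs at 500 permutations (an FWE estimate with
±0.015 standard error) and power on a 40-parcel cohort with an 8-region
perturbed clique at 1000 permutations; the lobe-block check against exact
enumeration on the 6-node case at 5000 permutations.

## Known limitations

- Runs are treated as exchangeable within subject strata; serial dependence
  between consecutive runs of a session is not modeled.
- The group models treat runs as independent observations given the subject
  covariate, mirroring the covariate-adjusted design they reproduce.
- Bonferroni at parcel level is conservative relative to voxelwise
  random-field FWE; absolute significance counts are not comparable to
  image-based analyses.
- Global-signal regression and scrubbing are deliberately excluded.
- Bit-level agreement with any particular fMRI toolbox's filter is neither
  attainable nor claimed; only the band is canonical.
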