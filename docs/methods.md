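# Methods

## The model

`faupa` analyses task fMRI through *functional areas of unitary pooled
activity* (FAUPAs): connected voxel sets whose BOLD signal shares one
temporal variation across the entire set. Unlike GLM mapping, FAUPA
detection needs no model of the task response — areas are found from
within-region temporal coherence alone — and task association is decided
afterwards by correlating each area's pooled time course with model
responses and with empirically selected reference areas.

The experimental design is a slow event-related paradigm: 24 trials, each a
6-s task period followed by 24 s of rest, cycling word-reading (WR),
pattern-viewing (PV) and finger-tapping (FT) eight times; TR = 2.5 s, 288
volumes (720 s). With three tasks there are seven possible task-association
categories (every non-empty subset of {WR, PV, FT}); a task's network is
the union of the four categories containing it.

### Ideal responses and the 0.8 threshold

The model ("ideal") response for a category is the union of its tasks'
on/off boxcars convolved with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, unit dispersions, undershoot ratio 1/6, 32-s support),
sampled directly on the TR grid (all onsets are TR multiples), linearly
convolved, truncated to 288 samples and mean-centered. Composite categories
use equal magnitudes per task, so before centering a composite response is
the sum of its single-task responses.

Pearson correlation is invariant to affine rescaling, so the mean-centered
series is equivalent to the percent-signal-change form for every
correlation computed here; the percent form is exposed only for plotting.

The 7x7 correlation table of the category responses is highly structured.
With r the common single-task pairwise correlation (cyclic symmetry of the
interleaved design makes the three pairs equal up to convolution edge
effects; a circular-convolution flag makes them exactly equal),
bilinearity of covariance gives closed forms for every composite entry,
e.g. corr(single, own pair) = sqrt((1+r)/2) and corr(pair, triple) =
(2+4r)/sqrt((2+2r)(3+6r)). At the computed r = -0.100 the maximum
off-diagonal entry is 0.770 (pair vs. overlapping triple). This is why the
category-assignment threshold defaults to R = 0.8: no category's exact
regressor can be captured by another category's reference at that
threshold. The table is computed on unfiltered regressors; bandpassing
them is available through the preprocessing module but changes the entries
negligibly.

### Preprocessing

Order: spatial Gaussian smoothing (default FWHM 4.0 mm at 3.5-mm voxels),
discrete-Fourier bandpass to 0.009-0.08 Hz (frequency mask: zero phase,
exactly idempotent, DC always removed), then conversion to percent signal
change. Because the bandpassed series has mean ~0, the percent conversion
divides the bandpassed deviation by the *pre-bandpass* temporal mean,
keeping percent units meaningful. Out-of-mask voxels carry NaN, never a
silent 0. The intensity mask keeps voxels whose temporal mean reaches a
fraction (default 0.3) of the robust (99th-percentile) maximum.

For simulated data the smoothing default is 0 mm: smoothing convolves the
planted ground truth itself — at zero noise a smoothed region's halo voxels
carry exactly the region time course, so the "true" region after smoothing
genuinely is the halo — which makes recovery-against-truth comparisons
meaningless. Smoothing exists to suppress scanner noise, which the
simulator does not model.

### FAUPA detection

Two criteria per candidate, applied to seeds in order of decreasing
neighbourhood homogeneity (mean correlation of each voxel with its face
neighbours, ties broken by voxel index — fully deterministic):

1. **Stable ROI growth.** From the seed, membership is repeatedly reset to
   the connected component (about the seed) of voxels whose correlation
   with the current ROI mean reaches `r_member`; iteration stops at a fixed
   point. Oscillation past `max_passes` (50), a seed falling below the
   floor against its own ROI mean, or a stable set smaller than `min_size`
   (4) discard the seed.

2. **Border criterion.** A stable ROI is a FAUPA only if pooled activity
   stops at its edge. Any border voxel reaching `r_member` against the ROI
   mean fails the ROI outright (the coherent area evidently continues);
   otherwise member correlations must exceed border correlations by a
   one-sided Mann-Whitney test at `border_alpha` = 0.01, falling back to a
   margin rule (max border R <= min member R - 0.1) when either side has
   fewer than 4 voxels.

Accepted FAUPAs claim their voxels, excluding them from later seeding and
growth; one run's FAUPAs are therefore pairwise disjoint and the whole
procedure is deterministic given the image and parameters.

**Choice of `r_member` = 0.5.** Growth bootstraps from a single voxel, so
on the first pass the gate is the *pairwise* voxel correlation, not the
member-to-mean correlation of an established region. For a coherent region
with in-band signal variance s^2, region-common noise c^2 and voxel-private
noise p^2, the pairwise correlation is (s^2+c^2)/(s^2+c^2+p^2) — about 0.58
at the harshest conditions the test suite exercises (peak SNR 1, half the
noise region-common) — while the steady-state member-to-mean correlation of
an n-voxel region is sqrt((s^2+c^2+p^2/n)/(s^2+c^2+p^2)) ~ 0.79. A floor
above ~0.55 starves growth at size 1; a floor of 0.5 sits below the
bootstrap gate yet more than 5 standard deviations above the correlation of
independent bandpassed voxels (0 +/- ~0.1 at ~100 effective samples), so
pure-noise seeds still die and no spurious FAUPA of size >= 4 survives (a
simulation check in the test suite confirms zero acceptances on noise-only
images). Default connectivity is face adjacency (6), configurable to 18/26.

### Task association

Per category, the detected FAUPA with maximal R to the category's ideal
response becomes the *representative*; a representative below
`validation_r` (0.8) is flagged and logged — the audit trail replacing a
visual inspection step. Classification then uses the representatives'
empirical time courses: each FAUPA receives the category of its
best-correlated representative if that R exceeds 0.8, else no category.
Argmax assignment keeps categories mutually exclusive; a `multi_assign`
flag restores plain per-category thresholding for audit. Activation maps
(voxelwise R against either an ideal response or a FAUPA time course,
thresholded at R > 0.45) support both reference styles.

### Trial dynamics

Trial windows span each full 30-s trial (task + rest; 12 samples), with an
optional integer-TR lag. Per-trial **activation** is the mean squared
percent change over the window (%^2) — BOLD magnitude scales roughly as the
square root of the underlying neural response, so squaring restores a
neural-activity-like scale. Per-trial **functional connectivity** is the
Pearson R of two pooled time courses within the window; a zero-variance
window propagates NaN (flagged, excluded from trial means with counts
reported). Task contrasts use classic equal-variance two-sample t-tests
(one- or two-tailed; Welch by flag); trial means average raw values
(Fisher-z by flag). Group summaries average within subject first, then
report across-subject mean and SEM.

Two R->p conventions are provided because printed p-values in this
literature follow two different recipes: the exact null t-test
(t = R sqrt(n-2)/sqrt(1-R^2), n-2 df — the default for inference, and the
one that reproduces p = 0.045 at R = 0.5864, n = 12) and the asymptotic
normal tail of z = R sqrt(N), which reproduces the very small printed
values at N = 288 (e.g. R = 0.8 -> 5.6e-42). Neither is claimed to be more
"correct"; both are labelled.

## The synthetic-data generator

Each planted region is a connected voxel set sharing one pooled time
course: the category's ideal response with per-trial log-normal amplitude
jitter (sigma_log 0.2), scaled so `amplitude_pct` is the peak percent
signal change, plus unit-variance AR(1) noise (lag-1 coefficient 0.3) of
total sd `sigma_pct`, split between a region-common stream (share 0.5) —
the pooled activity beyond the task response that makes a FAUPA a unit —
and voxel-private streams. Background voxels carry private noise only.
Null regions share common noise but no task response. Cohorts derive
per-subject seeds from one master seed and jitter region amplitudes
log-normally (sigma_log 0.1) across subjects.

Defaults (`amplitude_pct` 1.2, `sigma_pct` 0.35) are calibrated to the
observable statistics reported for this study design: after bandpassing
they yield on-task trial activation ~0.35 %^2 against an off-task floor of
~0.06 %^2, representative-to-ideal correlations ~0.87, and member and
assignment correlations that clear the 0.8 threshold — i.e. the regime in
which this kind of analysis demonstrably operates. The default grid is
24x24x12 voxels of 3.5 mm with baseline 1000 and one 8-voxel region per
category plus two null regions.

What the generator does *not* emulate: scanner artefacts (spikes, drift,
motion), physiological noise structure, spatial autocorrelation of noise
(optional smoothing of the noise field exists but is off by default),
anatomical geometry, and between-region correlation of ongoing activity.
Passing tests therefore show the algorithmic chain is correct and
well-calibrated under its own assumptions, not that it is robust to real
scanner data.

## Stress conditions and known limits

The test suite also exercises a deliberately harsh regime — peak SNR 1.0,
i.e. response peak equal to the total noise sd — where the method's
behaviour splits cleanly:

- **Detection survives.** Region-common noise is itself pooled activity,
  so within-region coherence stays high and recovery of planted voxel sets
  is essentially perfect (mean Jaccard 1.0 across seeds).
- **Classification does not.** With half the noise region-common, only
  ~27 % of a pooled time course's variance is task-locked; correlations to
  ideal responses drop to ~0.5, and with inter-category ideal correlations
  up to 0.774 the representative selection confuses overlapping categories
  (measured recovery ~57 % across 10 seeds; no common-noise share reaches
  95 % at this SNR). The fixed 0.8 assignment threshold is likewise
  unreachable between two same-category areas whose common noise is
  independent.
- **Per-trial significance weakens.** The 0.009-0.08 Hz passband leaves
  only ~4-5 effective noise samples per 30-s window, so per-trial
  activation and FC estimates are noisy; FT-vs-other contrasts point the
  right way every seed but reach one-tail p < 0.01 in only ~10-20 % of
  seeds.

These are properties of the statistics at that noise level, not
implementation defects; the corresponding assertions are kept in the
acceptance suite at their stated thresholds, and the same checks pass
decisively at the calibrated default regime (100 % category recovery;
median contrast p ~ 1e-8).

## Numerical and design choices

- Convolution is linear and truncated to the run; a circular flag exists
  for exact-symmetry checks. No microtime upsampling (onsets are TR
  multiples by design).
- Voxel coordinates are 0-based integer indices; window ranges half-open;
  TSV outputs carry a `#` unit comment line.
- Correlations are computed as dot products of unit-normalised centered
  series; zero-variance series raise or propagate NaN explicitly.
- Determinism: one master seed, per-subject seeds via `SeedSequence`
  (kept below 2^31), per-stage warnings captured into a JSON run manifest
  with output checksums, so any run is reproducible from its manifest.
- Degenerate inputs: empty masks, empty task sets, overlapping regions,
  misaligned onsets, non-positive means inside the mask, and zero-variance
  references all raise `ValueError` rather than degrade silently; an ROI
  with an empty in-mask border passes the border criterion vacuously with
  a logged warning.
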