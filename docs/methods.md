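# Methods

`vssr` re-implements, against a fully synthetic cohort, the analysis
chain used to measure visual steady-state entrainment in children who
are hard-of-hearing (CHH) versus children with normal hearing (CNH):
forward simulation of 15 Hz flicker responses, preprocessing,
complex-demodulation time–frequency analysis, two-stage cluster
permutation statistics, LCMV vector beamforming with virtual-sensor
envelope extraction, group × time mixed modeling, and
covariate-controlled whole-brain correlation mapping.  This note
records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic data can and cannot show.

## Forward model

A single-sphere conductor (radius 0.09 m, centered at the origin of a
common head frame shared by all synthetic subjects) carries current
dipoles whose external magnetic field follows the closed-form
spherical-conductor solution.  Sensors are 204 planar gradiometers —
102 helmet sites on a spherical cap of radius 0.102 m, two orthogonal
tangential gradiometer axes per site — each modeled as a two-point
finite difference of the field component along the coil orientation
across a 16.8 mm baseline.  Because the radial source component is
externally silent in a sphere, lead fields carry two tangential
columns per voxel; this also keeps the vector beamformer's 2×2 gain
matrix well conditioned.  Limitations: no realistic BEM/FEM anatomy,
no per-subject geometry, no magnetometers.

## Synthetic cohort

The generator plants, with per-subject ground truth retained for
parameter-recovery scoring:

* **Occipital entrainment source** (midline, near the posterior pole):
  sinusoids at 15 Hz and its 30 Hz harmonic (harmonic/fundamental
  amplitude ratio 0.5, base moment 25 nA·m).  The response begins
  ~100 ms after stimulus onset with a 50 ms raised-cosine rise (an
  instantaneous step would inject a broadband click no neural response
  contains), and decays exponentially (τ = 200 ms) after offset.
  During stimulation the amplitude follows
  `sqrt(1 + s·(t − onset))`, so *power* grows linearly at rate `s` —
  the scale on which the envelope statistics operate.  Group means:
  s = 2.105 /s (CHH) vs 1.050 /s (CNH), i.e. a planted difference of
  1.055 /s matching the magnitude of the reference group-by-time
  coefficient (−1.055 × 10⁻³ per ms in the source study's coding; our
  CHH = 1 coding makes the planted interaction positive).
  Between-subject slope SD 0.1 /s — deliberately modest, because the
  group × time model uses a random intercept only and larger slope
  heterogeneity would invalidate its Wald test (see calibration note
  below).
* **Cross-modal sources** in left auditory and left lateral parietal
  cortex (10 nA·m, 15 Hz, flat envelope, random phase per trial), with
  *power* gain
  `clip(1 − 0.6·z + N(0, 0.15²), 0.05, ∞)` where `z` is the
  standardized residual of weekly hearing-aid use on BEPTA: children
  who use their aids less than expected for their degree of hearing
  loss recruit these areas more.  CNH gains are small
  (N(0.15, 0.08²), floored at 0).  The coupling strength is a free
  parameter; the default is set so that the planted voxel-level
  partial correlation is strong (≈ −0.9), the regime the reference
  peak values (r ≈ −0.78 at n = 17) imply once one accounts for the
  fact that detection at p < .001 with 14 df requires |r| > 0.74.
  The cross-modal responses are *induced* rather than phase-locked:
  three mutually coherent sources would trigger the LCMV
  correlated-source cancellation pathology and leak group-dependent
  power into the occipital virtual sensor, and only the *power*
  coupling matters to the covariate analyses.  All three canonical
  locations sit on 8 mm-lattice coordinates so they coincide with
  voxels of the 4 and 8 mm reconstruction grids — a dominant source
  placed between grid points is partially cancelled at the nearest
  voxel by the adaptive filter (leadfield mismatch), which is a
  property of beamforming worth demonstrating but a poor default for
  recovery studies.
* **Covariates**: BEPTA uniform on 24–76 dB HL; weekly aid use
  `30.2 + 1.114·BEPTA + N(0, 23.6²)` clipped to [0, 112] h/week,
  giving the reference means/SDs and a BEPTA–use correlation near
  0.59; verbal standard scores centered at 103 (CHH) / 109 (CNH),
  with the CHH score coupled negatively (−6 points per SD) to the
  parietal cross-modal gain.
* **Noise**: 200 random tangential dipoles (8 nA·m RMS each) with 1/f
  amplitude spectra generated by a leaky integrator (flat below 1 Hz),
  plus white sensor noise (5 fT/(cm·sample)); 10% of trials receive a
  1–3 Hz artifact burst scaled 6–20× the clean-recording maximum with
  a random spatial pattern.  These levels put per-channel clean-epoch
  peaks near 1.5 pT/cm and individualized rejection thresholds in the
  1.2–1.7 × 10³ fT/cm range, the scale reported for real recordings.

Timing: 1 kHz sampling, 1.0 s flicker, inter-stimulus interval jittered
uniformly on 3.0–3.5 s, ≥ 0.9 s pre- and ≥ 2.0 s post-stimulus margin
around every event.

Two lighter generators plant the same effects directly at the level a
statistical stage consumes: `simulate_envelope_table` emits
relative-power envelopes (intercept N(2.0, 0.5²), bin noise SD 0.3 on
14 × 50 ms bins) for mixed-model studies, and `simulate_source_images`
emits pseudo-t images (Gaussian blobs of width 1.5 grid steps at the
three planted sites, voxel noise SD 0.4) for correlation-mapping
studies.  Monte-Carlo calibration loops run on these; the full
sensor-space chain is exercised once per end-to-end run.

What the synthetic data do **not** emulate: real artifact morphology
(blinks, cardiac), head movement, per-subject anatomy and sensor
geometry, line noise, inter-regional coupling, or non-sinusoidal
steady-state waveshape.  Passing recovery tests therefore demonstrates
the correctness and calibration of the *pipeline*, not properties of
any real population.

## Preprocessing

Zero-phase FIR high-pass at 0.3 Hz: the kernel is the spectral
complement of a unit-DC-gain low-pass (δ − lowpass, 4001 taps), which
nulls DC exactly while a directly designed high-pass of practical
length cannot; applied as a centered convolution (symmetric kernel ⇒
zero phase) with reflection padding.  SSP is available as an
orthogonal-projection operator (I − UUᵀ) and is recorded in
provenance; the default pipeline applies an empty projector set, since
the simulator produces no structured artifact subspace worth learning.
Epochs span −0.9 to 2.0 s around each flicker onset.

Artifact rejection is individualized per subject: per-trial peak
|amplitude| and peak |gradient| (first difference per ms) across all
channels, thresholded at **median + 3 × 1.4826·MAD** of each
statistic's own distribution (floored at the median; strict
inequality, so degenerate zero-spread distributions retain all
trials).  A mean + 3 SD rule was rejected: with any contamination
fraction the outliers inflate the SD until the threshold sits at the
artifact amplitude itself, rejecting (almost) nothing.  The resistant
rule retains 85–95 of 100 trials under the default 10% artifact rate,
matching the ~88/100 reported for real data.  The visual-inspection
supplement used on real data is, by nature, not reproduced.

## Time–frequency analysis

Complex demodulation: multiply by `exp(−i2πft)` (f from 2–100 Hz in
1 Hz steps; reduced ranges are a run-time configuration), smooth with
a zero-phase Gaussian FIR, square, double, average over trials, and
sample every 50 ms at bin centers.  Scaling: a unit-amplitude
sinusoid yields power 0.5 (= A²/2) in its own bin.  Power is averaged
over trials *after* squaring — demodulating a trial average would
cancel non-phase-locked activity (this ordering is asserted by test).

The smoothing kernel has a **1.0 Hz Gaussian spectral SD** (−6 dB at
≈1.18 Hz, σ_t ≈ 0.159 s, truncated at ±3σ_t, columns renormalized
near epoch edges).  This is the deliberate resolution compromise: a
kernel with half-power at 0.5 Hz (σ_t ≈ 0.37 s) leaks only ~1e-22 of
power 3 Hz away but smears the one-second entrainment envelope so
heavily that a planted linear power ramp of slope 2/s is recovered as
~1/s; the 1 Hz-SD kernel keeps ±3 Hz leakage at ~1e-4 (neighboring
analysis bins remain separated) while recovering the ramp slope to
~15% and the early/late power ratio to ~7%.  The first/last 0.1 s of
each epoch are flagged unreliable; all statistics windows are
interior.  Baseline normalization divides each bin by its own
channel × frequency mean power over −0.9 to −0.1 s.

## Sensor-space statistics

Stage 1: one-sample t-test of log normalized power against 0 at every
(channel, frequency, time) bin, thresholded two-sided at α = .05.
The log is used because power ratios are right-skewed and "no change"
is log = 0.  Stage 2: same-sign supra-threshold bins are clustered —
neighbors within ±1 frequency bin and ±1 time bin on the same or a
spatially adjacent sensor (coil positions within 4 cm) — and each
cluster's mass is its summed t.  The null records the maximum |mass|
over clusters per permutation under random sign-flips of the subject
maps (the exchangeable transformation for a one-sample design),
controlling family-wise error across all clusters; p-values use
add-one smoothing, and when the requested permutation count reaches
2^n_subjects the null is enumerated exhaustively.  Defaults: 5000
permutations (reduced in scaled runs).  Implementation notes: the
per-bin threshold |t| > t_crit is applied to sign-flipped column sums
via an algebraically equivalent per-bin bound on S², so permutations
never materialize full t-maps; components come from a union-find for
sparse supra sets and sparse-graph labeling for dense ones (identical
results, different cost profiles).

The imaging windows are selected from the significant clusters as the
tightest window covering the cluster at the target frequency, with the
band clipped to ±1 Hz; the end-to-end driver then images the
canonical 0.3–1.0 s × f₀±1 Hz windows after confirming a significant
cluster covers the target — the exact window-drawing rule applied to
real data is editorial, so the gate (a significant entrained cluster)
is what the pipeline enforces.

## Source imaging

Cross-spectral densities: Hann-tapered FFT cross-spectra per trial,
averaged over trials and over the band's frequency bins, for an active
window (0.3–1.0 s) and a passive window of equal duration and
bandwidth.  The passive window is **[−0.8, −0.1] s**: the stated
baseline (−0.9 to −0.1 s) is 0.8 s long, so a 0.7 s sub-window is
forced; it is pinned to the late baseline.

LCMV vector beamformer per voxel v with two-column lead field L:
`W = C⁻¹L(LᵀC⁻¹L)⁻¹` with `C = real(CSD_active + CSD_passive)/2`
plus diagonal loading of 5% of the mean sensor power (common weights
avoid bias between conditions; the loading fraction is exposed as
configuration).  The image value is noise-normalized differential
power, `pseudo_t = (P_act − P_pas) / (σ_n²·tr(WᵀW))`, with
`P = tr(Wᵀ·CSD·W)` and σ_n² the mean of the smallest quartile of C's
eigenvalues — the projected-white-noise normalization that makes
values comparable across the volume and invariant to overall data
rescaling.  Voxels with singular 2×2 gain (the sphere center) are
marked invalid.  Grand averages are voxel-wise means; peak finding
can be restricted to an anatomical search region (the end-to-end
driver restricts the entrainment peak to an occipital sphere of
2.5 cm radius, mirroring anatomy-guided peak reporting; whole-volume
argmax is the default).  Grid spacing defaults to 4 mm; scaled runs
use 8–10 mm.

Virtual sensors apply the voxel's weights to the epoched data,
yielding two orthogonal per-trial series; the retained orientation
maximizes mean 15 Hz power in the stimulation window (index 0, with a
logged note, for all-zero data).  Envelopes demodulate the retained
series with the same engine at 15 or 30 Hz, average power over
trials, and divide by the baseline mean; `fit_envelope_slope` recovers
the planted growth rate gain-invariantly as (fitted slope)/(fitted
value extrapolated to the 0.1 s onset).

## Group statistics

* **Covariates**: per-ear pure-tone average = mean of the 500/1000/
  2000/4000 Hz thresholds; BEPTA = better (lower) ear; weekly use =
  5×weekday + 2×weekend daily hours.  Missing thresholds raise — no
  imputation.
* **Entrainment mixed model**: relative power ~ group + time +
  group×time with a per-subject random intercept, REML (ML, then
  pooled OLS, as logged fallbacks), time in bin-center milliseconds
  (the scale on which the reference betas are printed), group coded
  CHH = 1.  Calibration: with a random intercept only, the
  interaction's Wald test is anticonservative if between-subject slope
  variance is large relative to bin noise; at the generator defaults
  (slope SD 0.1 /s, bin noise 0.3) the planted type-I rate is ≈ 0.05,
  which is asserted by a 500-replicate test.
* **Whole-brain mapping**: voxel-wise Pearson partial correlation
  (residual-on-residual) of pseudo-t with weekly use controlling
  BEPTA, two-sided p from t with df = n − 3; voxels at p < .001 are
  clustered by 6-face lattice adjacency separately by sign, and
  clusters of k ≥ 5 voxels are reported with their max-|r| peak.  A
  variable exactly explained by the control has zero residual
  variance; its partial correlation is reported as 0.
* **Peak–behavior**: Pearson r with df = n − 2, n ≥ 4 required.
* **Demographics**: pooled-variance two-sample t from group summary
  statistics; Pearson chi-square without continuity correction for
  sex and for handedness collapsed to right vs non-right.  No
  multiple-testing correction across the two frequencies or the
  behavioral correlations, matching the reporting convention of the
  reference analysis.

## Verification studies and problem sizes

`vssr.studies` packages the quantitative checks the acceptance script
and test suite run; sizes were chosen as the smallest that leave
Monte-Carlo standard errors well inside the decision margins:

* localization: 20 seeds, 20 trials each, 1 cm occipital slab grid;
* cluster FWE: 500 simulations × 200 permutations on a
  4 ch × 6 freq × 6 bin grid, 12 subjects;
* mixed model: 200 recovery replicates and 500 null replicates at
  23 + 17 subjects (envelope-level generator);
* cross-modal mapping: 50 + 50 seeds at n = 17 (image-level
  generator, 1 cm grid);
* end-to-end: one full run with 8 + 8 subjects, 24 trials, 3–40 Hz
  spectrograms, 8 mm grid, 300 permutations.

## Known limitations

Single-sphere conductor and shared geometry; generic artifact model;
demodulation resolution is a compromise (documented above) rather
than a match to any proprietary filter; the whole-brain correction
implements the k ≥ 5 extent rule operationally (no Gaussian-random-
field analytic p-values); envelope-level and image-level Monte-Carlo
generators bypass the forward model by design — the end-to-end run is
the only place the full chain is scored at once, and it checks signs,
not magnitudes.
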