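# vssr — visual steady-state MEG entrainment analysis

`vssr` is a self-contained re-implementation of an MEG analysis chain
for **visual steady-state (flicker-entrainment) responses** in
children who are hard-of-hearing (CHH) versus children with normal
hearing (CNH), paired with a synthetic-cohort generator so that every
stage can be exercised and verified without any data download.  It is
aimed at MEG methodologists and developmental-neurophysiology groups
who want a tested, fully synthetic testbed for this class of pipeline.

The chain, end to end:

1. **Forward simulation** — spherical-conductor dipole fields (Sarvas
   closed form) sampled by 204 planar gradiometers; an occipital
   source entrained at the 15 Hz flicker and its 30 Hz harmonic whose
   *power* grows linearly during stimulation with a group-dependent
   slope; left-auditory and left-parietal cross-modal sources whose
   power is coupled to hearing-aid use; 1/f background dipoles, sensor
   noise, artifact epochs, and correlated covariates (BEPTA, weekly
   aid use, verbal scores).
2. **Preprocessing** — 0.3 Hz zero-phase high-pass, optional SSP,
   2.9 s epochs (−0.9 to 2.0 s), individualized amplitude/gradient
   artifact rejection.
3. **Time–frequency** — complex demodulation (1 Hz resolution, 50 ms
   bins), baseline normalization by the −0.9 to −0.1 s window.
4. **Sensor statistics** — mass-univariate t-maps thresholded at
   p < .05, clustered over frequency, time, and 4 cm sensor
   neighborhoods; cluster mass = summed t; max-statistic sign-flip
   permutation null (≥ 5000 permutations at full scale).
5. **Source imaging** — frequency-domain LCMV vector beamformer,
   `W = C⁻¹L(LᵀC⁻¹L)⁻¹`, noise-normalized differential power
   `(P_act − P_pas)/(σ_n²·tr(WᵀW))` on a volumetric grid; virtual
   sensors (two orthogonal series, maximal response retained) and
   baseline-relative 15/30 Hz power envelopes at the grand-average
   peak.
6. **Group statistics** — linear mixed model
   `power ~ group * time + (1 | subject)` on 14 × 50 ms entrainment
   bins (0.3–1.0 s); whole-brain partial correlations between aid use
   and source power controlling BEPTA with a p < .001, k ≥ 5
   cluster-extent rule; peak–behavior correlations; demographic
   comparisons (pooled t, Pearson χ²).

`docs/methods.md` documents the models, defaults, and numerical
choices in detail.

## Worked example

The demonstration drivers under `analysis/` run the chain on a small
cohort (defaults: 5 CNH + 6 CHH subjects, 20 trials each):

```bash
python analysis/01_simulate_cohort.py --seed 7      # cohort.h5 + covariates
python analysis/02_preprocess.py                    # rejection log, retention
python analysis/03_sensor_stats.py --seed 7         # cluster test + quick-look
python analysis/04_source_imaging.py                # beamformer images, envelopes
python analysis/05_group_stats.py                   # LME, correlation maps
```

A full-scale run is one call; this is the configuration the
acceptance suite uses (8 + 8 subjects, 24 trials, 3–40 Hz
spectrograms, 8 mm grid, 300 permutations; ~4–8 min on one CPU):

```python
from vssr import pipeline, simulate

out = pipeline.run_all(
    simulate.CohortSpec(n_cnh=8, n_chh=8, n_trials=24, seed=42),
    config=pipeline.RunConfig(tfr_fmin=3, tfr_fmax=40,
                              grid_spacing=0.008, n_perm=300))
print(out["signs"])
print(out["lme"]["f0"].params)
```

Output from this exact run:

```
{'chh_slope_steeper': True, 'use_auditory_negative': True,
 'parietal_verbal_negative': True}
intercept        4.840984
group           -2.532488
time_ms          0.006293
group:time_ms    0.010351
```

Reading the numbers: the cluster test finds significant entrained
clusters at 15 and 30 Hz (the imaging gate); the grand-average 15 Hz
pseudo-t peak lands on the planted occipital voxel; the group × time
coefficient is **positive** (CHH = 1 coding: hard-of-hearing children
entrain with a steeper power slope, p ≈ 2 × 10⁻¹³ here), the partial
correlation between weekly hearing-aid use and auditory-cortex 15 Hz
power controlling BEPTA is **negative** (r ≈ −0.89: less aid use,
more cross-modal recruitment), and parietal cross-modal power
correlates **negatively** with verbal scores (r ≈ −0.64).  Slope
units are relative power per ms, so 0.0104/ms ≈ 10/s on this cohort's
envelope gain; on synthetic data the envelope's absolute gain is
SNR-dependent and only the sign pattern is the claim.

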