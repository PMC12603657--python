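"""Synthetic multi-subject MEG cohorts with known ground truth.

The generator emulates the statistical structure a visual-entrainment
study assumes, with every planted effect recoverable by the analysis
modules:

* occipital sources entrained at the 15 Hz flicker frequency and its
  30 Hz harmonic, whose *power* envelope grows linearly during
  stimulation with a group-dependent slope (hard-of-hearing cohorts
  steeper than normal-hearing ones);
* a left-auditory and a left-parietal cross-modal source whose power
  is negatively coupled to weekly hearing-aid use after conditioning
  on degree of hearing loss (better-ear pure-tone average, BEPTA);
* correlated subject covariates (BEPTA vs. hearing-aid use, verbal
  score vs. parietal cross-modal power);
* 1/f background activity from many random tangential dipoles, white
  sensor noise, and occasional high-amplitude artifact epochs.

Three generators operate at different levels of the pipeline.
``make_cohort`` produces full sensor-space recordings for end-to-end
runs.  ``simulate_envelope_table`` and ``simulate_source_images``
produce the same planted effects directly at the envelope and
source-image level, for Monte-Carlo studies of the statistical stages
where forward-simulating every replicate would add nothing but cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import (HeadModel, SensorArray, SourceGrid, default_sensor_array,
                      sarvas_dipole_field, tangential_basis)

__all__ = [
    "CohortSpec",
    "SourceSpec",
    "SubjectTruth",
    "EffectConfig",
    "NoiseParams",
    "Recording",
    "default_sources",
    "entrainment_source_waveform",
    "source_gain",
    "simulate_subject_recording",
    "draw_subject_truths",
    "make_cohort",
    "simulate_envelope_table",
    "simulate_source_images",
    "OCCIPITAL_LOC",
    "AUDITORY_LOC",
    "PARIETAL_LOC",
]

# Canonical planted locations (head frame, m): midline occipital pole,
# left temporal (auditory), left lateral parietal.  Coordinates are
# multiples of 8 mm so the sources coincide with voxels of the 4 and
# 8 mm reconstruction lattices: a strong source falling between grid
# points is partially cancelled by an adaptive beamformer (leadfield
# mismatch), which is a property of the method, not a useful default.
OCCIPITAL_LOC = np.array([0.0, -0.072, 0.008])
AUDITORY_LOC = np.array([-0.056, -0.008, 0.008])
PARIETAL_LOC = np.array([-0.048, -0.032, 0.056])


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters: sample sizes, trial count, timing."""

    n_cnh: int
    n_chh: int
    n_trials: int = 100
    sampling_rate: float = 1000.0
    stim_duration: float = 1.0
    isi_range: tuple[float, float] = (3.0, 3.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_cnh <= 0 or self.n_chh <= 0 or self.n_trials <= 0:
            raise ValueError("counts must be positive")
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("isi_range must be ordered")


@dataclass(frozen=True)
class SourceSpec:
    """One entrained dipolar source.

    ``orientation`` gives the two coefficients of the dipole direction
    on the local tangential basis at ``location``.  During stimulation
    the instantaneous amplitude follows
    ``base_amplitude * sqrt(1 + envelope_slope * (t - onset))`` so that
    *power* grows linearly in time — the scale on which the envelope
    statistics operate.
    """

    location: np.ndarray
    orientation: tuple[float, float] = (1.0, 0.0)
    f0: float = 15.0
    harmonic_gain: float = 0.5
    onset_latency: float = 0.1
    base_amplitude: float = 25e-9     # A·m
    envelope_slope: float = 0.0       # relative power / s
    offset_decay: float = 0.2         # s
    onset_ramp: float = 0.05          # s, raised-cosine rise

    def __post_init__(self):
        object.__setattr__(self, "location",
                           np.asarray(self.location, dtype=float))
        if self.f0 <= 0 or self.onset_latency < 0 or self.base_amplitude < 0:
            raise ValueError("invalid source parameters")


@dataclass
class SubjectTruth:
    """Ground truth planted for one simulated subject."""

    subject_id: str
    group: str                       # "CNH" or "CHH"
    occipital_slope: float           # relative power / s
    auditory_gain: float             # power gain of the auditory source
    parietal_gain: float
    bepta: float                     # dB HL (NaN for CNH)
    ha_use: float                    # hours/week (NaN for CNH)
    verbal_score: float
    age: float
    sex: str


@dataclass(frozen=True)
class EffectConfig:
    """Population-level effect sizes and covariate distributions.

    Slope means put the group difference at 1.055 relative-power/s
    (hard-of-hearing steeper), on the scale of the study this emulates;
    covariate parameters reproduce a BEPTA distribution on 24–76 dB HL
    and hearing-aid use of about 80 ± 29 h/week correlated ~0.59 with
    BEPTA.  Cross-modal power gain decreases with use residualized on
    BEPTA (coefficient ``crossmodal_a1`` per SD of residual), and the
    verbal score decreases with parietal cross-modal gain.
    """

    slope_mean_cnh: float = 1.050
    slope_mean_chh: float = 2.105
    slope_sd: float = 0.10
    bepta_range: tuple[float, float] = (24.0, 76.0)
    ha_intercept: float = 30.2       # h/week at 0 dB HL
    ha_slope: float = 1.114          # h/week per dB
    ha_noise_sd: float = 23.6
    ha_max: float = 112.0
    crossmodal_a0: float = 1.0
    crossmodal_a1: float = 0.6
    crossmodal_noise_sd: float = 0.15
    crossmodal_floor: float = 0.05
    cnh_crossmodal_mean: float = 0.15
    cnh_crossmodal_sd: float = 0.08
    vci_mean_cnh: float = 109.0
    vci_sd_cnh: float = 13.0
    vci_mean_chh: float = 103.4
    vci_parietal_coupling: float = 6.0   # points per SD of parietal gain
    vci_noise_sd_chh: float = 8.0

    def __post_init__(self):
        if self.slope_sd <= 0 or self.ha_noise_sd <= 0:
            raise ValueError("variance parameters must be positive")
        if self.crossmodal_noise_sd <= 0 or self.cnh_crossmodal_sd <= 0:
            raise ValueError("variance parameters must be positive")
        if self.crossmodal_a1 < 0:
            raise ValueError("crossmodal coupling must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Background and artifact model for sensor-space recordings."""

    n_noise_dipoles: int = 200
    noise_dipole_rms: float = 8e-9    # A·m per dipole
    sensor_noise_sd: float = 5e-12    # T/m
    artifact_fraction: float = 0.1
    artifact_scale_range: tuple[float, float] = (6.0, 20.0)
    artifact_duration: float = 0.5    # s
    artifact_freq_range: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self):
        if self.noise_dipole_rms <= 0 or self.sensor_noise_sd <= 0:
            raise ValueError("noise amplitudes must be positive")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must be in [0, 1)")


@dataclass
class Recording:
    """Continuous multichannel gradiometer recording with event markers."""

    data: np.ndarray                 # channels × samples, T/m
    sampling_rate: float
    events: np.ndarray               # (n_events, 2): sample index, code
    subject_id: str
    provenance: list[str] = field(default_factory=list)


def default_sources(effect: EffectConfig | None = None) -> dict[str, SourceSpec]:
    """Canonical three-source layout used by the cohort generator."""
    return {
        "occipital": SourceSpec(OCCIPITAL_LOC, base_amplitude=25e-9),
        "auditory": SourceSpec(AUDITORY_LOC, base_amplitude=10e-9,
                               harmonic_gain=0.0),
        "parietal": SourceSpec(PARIETAL_LOC, base_amplitude=10e-9,
                               harmonic_gain=0.0),
    }


def entrainment_source_waveform(spec: SourceSpec, trial_duration: float,
                                sampling_rate: float,
                                stim_duration: float = 1.0,
                                phase: float = 0.0) -> np.ndarray:
    """Dipole moment time series (A·m) for one stimulation trial.

    Zero before ``onset_latency``; amplitude
    ``base_amplitude * sqrt(1 + envelope_slope * (t - onset))`` during
    stimulation (linear *power* growth); exponential decay with time
    constant ``offset_decay`` after stimulus offset.  A raised-cosine
    ramp of ``onset_ramp`` seconds smooths the response onset — an
    instantaneous step would inject broadband energy no neural
    response contains.
    """
    t_end = spec.onset_latency + stim_duration
    if trial_duration < t_end + spec.offset_decay:
        raise ValueError("trial_duration does not cover the response")
    n = int(round(trial_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    rel_power = 1.0 + spec.envelope_slope * (t - spec.onset_latency)
    if np.any(rel_power[(t >= spec.onset_latency) & (t <= t_end)] < 0):
        warnings.warn("envelope clipped at zero power", stacklevel=2)
    amp = np.sqrt(np.clip(rel_power, 0.0, None)) * spec.base_amplitude
    amp[t < spec.onset_latency] = 0.0
    if spec.onset_ramp > 0:
        ramping = ((t >= spec.onset_latency)
                   & (t < spec.onset_latency + spec.onset_ramp))
        phase_r = (t[ramping] - spec.onset_latency) / spec.onset_ramp
        amp[ramping] *= 0.5 * (1.0 - np.cos(np.pi * phase_r))
    post = t > t_end
    amp_end = np.sqrt(max(1.0 + spec.envelope_slope * stim_duration, 0.0))
    amp[post] = (spec.base_amplitude * amp_end
                 * np.exp(-(t[post] - t_end) / spec.offset_decay))
    arg = 2.0 * np.pi * spec.f0 * (t - spec.onset_latency) + phase
    carrier = np.sin(arg) + spec.harmonic_gain * np.sin(2.0 * arg)
    return amp * carrier


def source_gain(location: np.ndarray, orientation: tuple[float, float],
                head: HeadModel, sensors: SensorArray) -> np.ndarray:
    """Per-channel gain of a unit tangential dipole at ``location``."""
    radial = location - head.sphere_center
    radial = radial / np.linalg.norm(radial)
    t1, t2 = tangential_basis(radial)
    direction = orientation[0] * t1 + orientation[1] * t2
    direction = direction / np.linalg.norm(direction)
    return sarvas_dipole_field(location, direction, head, sensors)


def _one_over_f_series(rng: np.random.Generator, n_series: int,
                       n_samples: int, sampling_rate: float,
                       corner_hz: float = 1.0) -> np.ndarray:
    """Unit-RMS rows with 1/f amplitude spectra, flat below ``corner_hz``.

    A leaky integrator driven by white noise: the amplitude response is
    proportional to 1/sqrt(corner² + f²), i.e. 1/f above the corner.
    O(n) and numerically cheap even for long recordings.
    """
    from scipy import signal as sp_signal
    pole = np.exp(-2.0 * np.pi * corner_hz / sampling_rate)
    white = rng.standard_normal((n_series, n_samples))
    out = sp_signal.lfilter([1.0], [1.0, -pole], white, axis=1)
    rms = np.sqrt(np.einsum("ij,ij->i", out, out) / n_samples)
    return out / np.where(rms > 0, rms, 1.0)[:, None]


def simulate_subject_recording(truth: SubjectTruth, cohort: CohortSpec,
                               head: HeadModel, sensors: SensorArray,
                               sources: dict[str, SourceSpec] | None = None,
                               noise: NoiseParams | None = NoiseParams(),
                               seed: int | None = None) -> Recording:
    """Continuous recording for one subject: sources + noise + artifacts.

    The occipital envelope slope is taken from ``truth``; the auditory
    and parietal source amplitudes are scaled by the square root of the
    subject's cross-modal power gains.  Pass ``noise=None`` for a
    noise-free projection of the sources alone.
    """
    sources = sources or default_sources()
    fs = cohort.sampling_rate
    f_max = 2.0 * max(s.f0 for s in sources.values())
    if fs < 4.0 * f_max:
        raise ValueError("sampling rate below 4× highest simulated frequency")
    rng = np.random.default_rng(seed)

    pre, post = 1.0, 2.2
    isis = rng.uniform(*cohort.isi_range, size=cohort.n_trials - 1)
    onsets_s = pre + np.concatenate(
        [[0.0], np.cumsum(cohort.stim_duration + isis)])
    n_samples = int(round((onsets_s[-1] + cohort.stim_duration + post) * fs))
    onset_samples = np.round(onsets_s * fs).astype(int)
    events = np.column_stack([onset_samples,
                              np.ones_like(onset_samples)])

    data = np.zeros((sensors.n_channels, n_samples))
    trial_dur = cohort.stim_duration + 1.0
    gains_used: dict[str, float] = {
        "occipital": 1.0,
        "auditory": np.sqrt(max(truth.auditory_gain, 0.0)),
        "parietal": np.sqrt(max(truth.parietal_gain, 0.0)),
    }
    for name, spec in sources.items():
        scale = gains_used.get(name, 1.0)
        if scale == 0.0:
            continue
        g = source_gain(spec.location, spec.orientation, head, sensors)
        if name == "occipital":
            # phase-locked to the flicker, identical every trial
            spec = replace(spec, envelope_slope=truth.occipital_slope)
            wave = scale * entrainment_source_waveform(
                spec, trial_dur, fs, cohort.stim_duration)
            block = g[:, None] * wave[None, :]
            for s0 in onset_samples:
                s1 = min(s0 + len(wave), n_samples)
                data[:, s0:s1] += block[:, :s1 - s0]
        else:
            # cross-modal sources carry an induced (non-phase-locked)
            # response: a random phase per trial preserves the power
            # coupling while avoiding coherence with the occipital
            # source, which would bias the beamformer (correlated
            # sources partially cancel under LCMV)
            phases = rng.uniform(0.0, 2.0 * np.pi, cohort.n_trials)
            for s0, ph in zip(onset_samples, phases):
                wave = scale * entrainment_source_waveform(
                    spec, trial_dur, fs, cohort.stim_duration, phase=ph)
                s1 = min(s0 + len(wave), n_samples)
                data[:, s0:s1] += g[:, None] * wave[None, :s1 - s0]

    if noise is not None:
        series = _one_over_f_series(rng, noise.n_noise_dipoles, n_samples, fs)
        series *= noise.noise_dipole_rms
        G = np.empty((sensors.n_channels, noise.n_noise_dipoles))
        R = head.sphere_radius
        for d in range(noise.n_noise_dipoles):
            while True:
                pos = head.sphere_center + rng.uniform(-0.8 * R, 0.8 * R, 3)
                if np.linalg.norm(pos - head.sphere_center) < 0.8 * R:
                    break
            ang = rng.uniform(0, 2 * np.pi)
            G[:, d] = source_gain(pos, (np.cos(ang), np.sin(ang)),
                                  head, sensors)
        data += G @ series
        data += noise.sensor_noise_sd * rng.standard_normal(data.shape)

        n_art = int(round(noise.artifact_fraction * cohort.n_trials))
        if n_art:
            clean_max = np.abs(data).max()
            art_trials = rng.choice(cohort.n_trials, n_art, replace=False)
            n_burst = int(round(noise.artifact_duration * fs))
            win = np.hanning(n_burst)
            for tr in sorted(art_trials):
                f_art = rng.uniform(*noise.artifact_freq_range)
                scale = rng.uniform(*noise.artifact_scale_range)
                center = rng.uniform(-0.4, 1.5)
                tb = np.arange(n_burst) / fs
                burst = win * np.sin(2 * np.pi * f_art * tb)
                pattern = rng.standard_normal(sensors.n_channels)
                pattern /= np.abs(pattern).max()
                s0 = onset_samples[tr] + int(round((center - 0.25) * fs))
                s0 = max(0, min(s0, n_samples - n_burst))
                data[:, s0:s0 + n_burst] += (scale * clean_max
                                             * pattern[:, None] * burst)

    return Recording(data, fs, events, truth.subject_id,
                     provenance=[f"simulate(seed={seed})"])


def draw_subject_truths(spec: CohortSpec,
                        effect: EffectConfig | None = None,
                        seed: int | None = None
                        ) -> tuple[list[SubjectTruth], pd.DataFrame]:
    """Sample per-subject ground truth and the covariate table.

    Hard-of-hearing subjects get BEPTA ~ uniform on ``bepta_range``,
    hearing-aid use linear in BEPTA plus noise (clipped to
    [0, ha_max]), and cross-modal power gains
    ``a0 - a1 * z + noise`` (floored) where ``z`` is the standardized
    residual of use on BEPTA — so less use than expected for one's
    hearing loss means more cross-modal recruitment.
    """
    effect = effect or EffectConfig()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    truths: list[SubjectTruth] = []

    n_chh = spec.n_chh
    bepta = rng.uniform(*effect.bepta_range, size=n_chh)
    ha = (effect.ha_intercept + effect.ha_slope * bepta
          + effect.ha_noise_sd * rng.standard_normal(n_chh))
    ha = np.clip(ha, 0.0, effect.ha_max)
    # residual of use on BEPTA (the unique auditory-experience signal)
    X = np.column_stack([np.ones(n_chh), bepta])
    beta, *_ = np.linalg.lstsq(X, ha, rcond=None)
    resid = ha - X @ beta
    rsd = resid.std()
    z = resid / rsd if rsd > 0 else np.zeros(n_chh)

    def crossmodal_gain(n, zz):
        g = (effect.crossmodal_a0 - effect.crossmodal_a1 * zz
             + effect.crossmodal_noise_sd * rng.standard_normal(n))
        return np.clip(g, effect.crossmodal_floor, None)

    aud = crossmodal_gain(n_chh, z)
    par = crossmodal_gain(n_chh, z)
    par_z = (par - par.mean()) / max(par.std(), 1e-12)
    vci_chh = (effect.vci_mean_chh
               - effect.vci_parietal_coupling * par_z
               + effect.vci_noise_sd_chh * rng.standard_normal(n_chh))

    for i in range(n_chh):
        truths.append(SubjectTruth(
            subject_id=f"chh{i:03d}", group="CHH",
            occipital_slope=effect.slope_mean_chh
            + effect.slope_sd * rng.standard_normal(),
            auditory_gain=float(aud[i]), parietal_gain=float(par[i]),
            bepta=float(bepta[i]), ha_use=float(ha[i]),
            verbal_score=float(vci_chh[i]),
            age=float(rng.uniform(7.2, 15.9)),
            sex="M" if rng.random() < 0.62 else "F"))

    for i in range(spec.n_cnh):
        g_aud = max(effect.cnh_crossmodal_mean
                    + effect.cnh_crossmodal_sd * rng.standard_normal(), 0.0)
        g_par = max(effect.cnh_crossmodal_mean
                    + effect.cnh_crossmodal_sd * rng.standard_normal(), 0.0)
        truths.append(SubjectTruth(
            subject_id=f"cnh{i:03d}", group="CNH",
            occipital_slope=effect.slope_mean_cnh
            + effect.slope_sd * rng.standard_normal(),
            auditory_gain=g_aud, parietal_gain=g_par,
            bepta=np.nan, ha_use=np.nan,
            verbal_score=float(effect.vci_mean_cnh
                               + effect.vci_sd_cnh * rng.standard_normal()),
            age=float(rng.uniform(7.2, 15.9)),
            sex="M" if rng.random() < 0.65 else "F"))

    hand = rng.choice(["R", "L", "Am"], size=len(truths),
                      p=[0.85, 0.12, 0.03])
    cov = pd.DataFrame([{
        "subject_id": t.subject_id, "group": t.group, "age": t.age,
        "sex": t.sex, "handedness": h, "bepta": t.bepta,
        "ha_use": t.ha_use, "verbal_score": t.verbal_score,
    } for t, h in zip(truths, hand)])
    return truths, cov


def make_cohort(spec: CohortSpec, effect: EffectConfig | None = None,
                head: HeadModel | None = None,
                sensors: SensorArray | None = None,
                sources: dict[str, SourceSpec] | None = None,
                noise: NoiseParams | None = NoiseParams(),
                with_recordings: bool = True):
    """Sample a cohort: ground truth, recordings, covariate table."""
    head = head or HeadModel()
    sensors = sensors or default_sensor_array(head=head)
    truths, cov = draw_subject_truths(spec, effect, seed=spec.seed)
    recordings: list[Recording] = []
    if with_recordings:
        root = np.random.SeedSequence(spec.seed)
        child_seeds = root.generate_state(len(truths)) % (2 ** 31)
        for t, s in zip(truths, child_seeds):
            recordings.append(simulate_subject_recording(
                t, spec, head, sensors, sources, noise, seed=int(s)))
    return truths, recordings, cov


def simulate_envelope_table(truths: list[SubjectTruth],
                            seed: int | None = None,
                            intercept_mean: float = 2.0,
                            intercept_sd: float = 0.5,
                            noise_sd: float = 0.3,
                            window: tuple[float, float] = (0.3, 1.0),
                            bin_width: float = 0.05) -> pd.DataFrame:
    """Long-format relative-power envelope table, one row per bin.

    Emulates the per-subject baseline-relative 15 Hz power envelope at
    the envelope level: ``intercept_i + slope_i * (t - window[0])``
    plus independent bin noise, sampled at the 50 ms bin centers of the
    entrainment window (14 bins for 0.3–1.0 s).  ``time_ms`` holds bin
    centers in milliseconds, the unit the mixed model uses.
    """
    from .tfr import entrainment_bin_centers
    rng = np.random.default_rng(seed)
    centers = entrainment_bin_centers(window[0], window[1], bin_width)
    rows = []
    for t in truths:
        a = intercept_mean + intercept_sd * rng.standard_normal()
        rel = (a + t.occipital_slope * (centers - window[0])
               + noise_sd * rng.standard_normal(len(centers)))
        for tm, v in zip(centers * 1000.0, rel):
            rows.append((t.subject_id, t.group, tm, v))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "time_ms", "relative_power"])


def simulate_source_images(truths: list[SubjectTruth], grid: SourceGrid,
                           seed: int | None = None,
                           occipital_amp: float = 6.0,
                           crossmodal_amp: float = 3.0,
                           voxel_noise_sd: float = 0.4,
                           blob_sigma_factor: float = 1.5) -> np.ndarray:
    """Per-subject pseudo-t source images with planted spatial blobs.

    Each image is a sum of Gaussian blobs (width ``blob_sigma_factor``
    grid steps) at the canonical occipital, auditory, and parietal
    locations, scaled by the subject's planted gains, plus independent
    voxel noise.  Returns (n_subjects, n_voxels).
    """
    rng = np.random.default_rng(seed)
    sigma = blob_sigma_factor * grid.spacing

    def blob(center):
        d2 = ((grid.voxel_coords - center) ** 2).sum(axis=1)
        return np.exp(-0.5 * d2 / sigma ** 2)

    b_occ, b_aud, b_par = (blob(OCCIPITAL_LOC), blob(AUDITORY_LOC),
                           blob(PARIETAL_LOC))
    images = np.empty((len(truths), grid.n_voxels))
    for i, t in enumerate(truths):
        occ = occipital_amp * (1.0 + 0.2 * rng.standard_normal())
        images[i] = (occ * b_occ
                     + crossmodal_amp * t.auditory_gain * b_aud
                     + crossmodal_amp * t.parietal_gain * b_par
                     + voxel_noise_sd * rng.standard_normal(grid.n_voxels))
    return images
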