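"""Frequency-domain LCMV vector beamforming and virtual sensors.

Per voxel v with two-column tangential lead field L, the spatial
filter is ``W = C⁻¹ L (Lᵀ C⁻¹ L)⁻¹`` with C the (regularized) real
part of the averaged active/passive cross-spectral density — the
linearly constrained minimum-variance solution with unit gain
``Wᵀ L = I``.  Source power in a band/window is ``tr(Wᵀ CSD W)``; the
image value is noise-normalized differential power (a pseudo-t),

    (P_active − P_passive) / (σ_n² · tr(Wᵀ W)),

with σ_n² estimated as the mean of the smallest quartile of C's
eigenvalues.  The denominator is the filter's projected white-noise
power, which makes values comparable across the volume and invariant
to an overall rescaling of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import LeadField, SourceGrid
from .preprocess import Epochs
from .tfr import demodulated_power, entrainment_bin_centers

__all__ = [
    "CrossSpectralDensity",
    "SourceImage",
    "LcmvResult",
    "VirtualSensorSeries",
    "EnvelopeSeries",
    "compute_csd",
    "lcmv_image",
    "grand_average_and_peak",
    "extract_virtual_sensor",
    "envelope_timeseries",
    "fit_envelope_slope",
    "envelope_long_table",
]

logger = logging.getLogger(__name__)


@dataclass
class CrossSpectralDensity:
    """Trial-averaged sensor cross-spectra over a band and window."""

    matrix: np.ndarray               # channels × channels, complex
    band: tuple[float, float]
    window: tuple[float, float]
    n_trials: int


@dataclass
class SourceImage:
    """Noise-normalized differential power (pseudo-t) per grid voxel."""

    pseudo_t: np.ndarray             # (n_voxels,) — NaN at invalid voxels
    grid: SourceGrid
    band: tuple[float, float]
    active_window: tuple[float, float]
    passive_window: tuple[float, float]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.pseudo_t)

    def peak_voxel(self, mask: np.ndarray | None = None) -> int:
        vals = np.where(self.valid, self.pseudo_t, -np.inf)
        if mask is not None:
            vals = np.where(mask, vals, -np.inf)
        return int(np.argmax(vals))


@dataclass
class LcmvResult:
    """Image plus the spatial filters that produced it."""

    image: SourceImage
    weights: np.ndarray              # (n_voxels, n_channels, 2)


@dataclass
class VirtualSensorSeries:
    """Per-trial source time series at one voxel (two orientations)."""

    series: np.ndarray               # trials × 2 × samples
    chosen_orientation: int
    voxel: int
    time_axis: np.ndarray
    sampling_rate: float

    @property
    def chosen(self) -> np.ndarray:
        return self.series[:, self.chosen_orientation, :]


@dataclass
class EnvelopeSeries:
    """Baseline-relative power at one frequency vs. time (50 ms bins)."""

    values: np.ndarray
    time_axis: np.ndarray
    freq: float
    baseline_window: tuple[float, float]


def compute_csd(epochs: Epochs, band: tuple[float, float],
                window: tuple[float, float]) -> CrossSpectralDensity:
    """Hann-windowed Fourier cross-spectra, averaged over band and trials."""
    fs = epochs.sampling_rate
    if band[1] >= fs / 2:
        raise ValueError("band extends to or beyond Nyquist")
    mask = (epochs.time_axis >= window[0]) & (epochs.time_axis < window[1])
    n = int(mask.sum())
    if band[0] > 0 and n < fs / band[0]:
        raise ValueError("window shorter than one cycle of the band edge")
    taper = np.hanning(n)
    seg = epochs.data[:, :, mask] * taper
    F = np.fft.rfft(seg, axis=2)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    fbins = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if fbins.size == 0:
        fbins = np.array([np.argmin(np.abs(freqs - np.mean(band)))])
    scale = 2.0 / (fs * (taper ** 2).sum())
    Fb = F[:, :, fbins]                         # trials × ch × bins
    csd = scale * np.einsum("tcb,tdb->cd", Fb, Fb.conj()) \
        / (epochs.n_trials * fbins.size)
    csd = 0.5 * (csd + csd.conj().T)
    return CrossSpectralDensity(csd, tuple(band), tuple(window),
                                epochs.n_trials)


def lcmv_image(csd_active: CrossSpectralDensity,
               csd_passive: CrossSpectralDensity,
               leadfield: LeadField,
               regularization: float = 0.05) -> LcmvResult:
    """LCMV vector-beamformer pseudo-t image over the source grid.

    ``regularization`` is the diagonal loading as a fraction of mean
    sensor power (mean eigenvalue of C).  Voxels with a (near-)singular
    ``Lᵀ C⁻¹ L`` — e.g. the sphere center — are marked invalid (NaN).
    """
    dur_a = csd_active.window[1] - csd_active.window[0]
    dur_p = csd_passive.window[1] - csd_passive.window[0]
    if abs(dur_a - dur_p) > 1e-9:
        raise ValueError("active and passive windows must have equal duration")
    bw_a = csd_active.band[1] - csd_active.band[0]
    bw_p = csd_passive.band[1] - csd_passive.band[0]
    if abs(bw_a - bw_p) > 1e-9:
        raise ValueError("active and passive bands must have equal bandwidth")

    Ca = csd_active.matrix.real
    Cp = csd_passive.matrix.real
    C = 0.5 * (Ca + Cp)
    n_ch = C.shape[0]
    mean_power = np.trace(C) / n_ch
    C = C + regularization * mean_power * np.eye(n_ch)

    eig = np.linalg.eigvalsh(C)
    q = max(1, n_ch // 4)
    sigma_n2 = float(eig[:q].mean())
    Cinv = np.linalg.inv(C)

    L = leadfield.matrix                        # (nv, nch, 2)
    A = np.einsum("cd,vdk->vck", Cinv, L)
    M = np.einsum("vck,vcl->vkl", L, A)         # (nv, 2, 2)
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    norm = np.maximum(np.abs(M).max(axis=(1, 2)), 1e-300) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = np.abs(det) / norm > 1e-12
    Minv = np.empty_like(M)
    safe_det = np.where(valid, det, 1.0)
    Minv[:, 0, 0] = M[:, 1, 1] / safe_det
    Minv[:, 1, 1] = M[:, 0, 0] / safe_det
    Minv[:, 0, 1] = -M[:, 0, 1] / safe_det
    Minv[:, 1, 0] = -M[:, 1, 0] / safe_det
    W = np.einsum("vck,vkl->vcl", A, Minv)      # (nv, nch, 2)

    def band_power(Cx):
        # tr(Wᵀ Cx W) per voxel
        return np.einsum("vck,cd,vdk->v", W, Cx, W, optimize=True)

    p_act = band_power(Ca)
    p_pas = band_power(Cp)
    noise_proj = sigma_n2 * np.einsum("vck,vck->v", W, W)
    with np.errstate(invalid="ignore", divide="ignore"):
        pseudo_t = (p_act - p_pas) / noise_proj
    pseudo_t[~valid] = np.nan
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("%d voxels invalid (singular gain matrix)", n_bad)
    img = SourceImage(pseudo_t, leadfield.grid, csd_active.band,
                      csd_active.window, csd_passive.window)
    return LcmvResult(img, W)


def grand_average_and_peak(images: list[SourceImage],
                           mask: np.ndarray | None = None
                           ) -> tuple[SourceImage, int]:
    """Voxel-wise mean image across subjects and its peak voxel.

    Ties break to the lowest voxel index (argmax convention).
    """
    ref = images[0]
    for im in images[1:]:
        if im.grid.n_voxels != ref.grid.n_voxels or \
                not np.allclose(im.grid.voxel_coords, ref.grid.voxel_coords):
            raise ValueError("images are on mismatched grids")
    mean = np.mean([im.pseudo_t for im in images], axis=0)
    out = SourceImage(mean, ref.grid, ref.band, ref.active_window,
                      ref.passive_window)
    return out, out.peak_voxel(mask)


def extract_virtual_sensor(result: LcmvResult, voxel: int,
                           epochs: Epochs,
                           f0: float = 15.0,
                           stim_window: tuple[float, float] = (0.3, 1.0)
                           ) -> VirtualSensorSeries:
    """Project epochs through the beamformer weights at one voxel.

    Yields two orthogonal source time series per trial; the retained
    orientation is the one with the larger mean power at ``f0`` inside
    the stimulation window.
    """
    if not np.isfinite(result.image.pseudo_t[voxel]):
        raise ValueError(f"voxel {voxel} is invalid")
    W = result.weights[voxel]                   # (nch, 2)
    series = np.einsum("ck,tcs->tks", W, epochs.data)
    if not np.any(series):
        logger.info("zero data: defaulting to orientation 0")
        chosen = 0
    else:
        centers = entrainment_bin_centers(*stim_window)
        power = demodulated_power(series, epochs.time_axis,
                                  epochs.sampling_rate, f0, centers)
        chosen = int(np.argmax(power.mean(axis=(0, 2))))
    return VirtualSensorSeries(series, chosen, voxel, epochs.time_axis,
                               epochs.sampling_rate)


def envelope_timeseries(vs: VirtualSensorSeries, freq: float,
                        baseline: tuple[float, float] = (-0.9, -0.1),
                        time_step: float = 0.05) -> EnvelopeSeries:
    """Baseline-relative power envelope at ``freq`` (trial-averaged)."""
    t0, t1 = vs.time_axis[0], vs.time_axis[-1]
    n = int(np.floor((t1 - t0) / time_step + 1e-9))
    centers = t0 + time_step * (np.arange(n) + 0.5)
    power = demodulated_power(vs.chosen, vs.time_axis, vs.sampling_rate,
                              freq, centers).mean(axis=0)
    bmask = (centers >= baseline[0]) & (centers <= baseline[1])
    base = power[bmask].mean()
    if not base > 0:
        raise ValueError("zero baseline power")
    return EnvelopeSeries(power / base, centers, freq, tuple(baseline))


def fit_envelope_slope(env: EnvelopeSeries,
                       window: tuple[float, float] = (0.3, 1.0),
                       onset: float = 0.1) -> float:
    """Relative slope of the envelope over the entrainment window.

    Fits a line over the window and normalizes the fitted slope by the
    fitted value extrapolated to the response onset, recovering the
    planted relative-power growth rate (per second) independent of the
    envelope's overall gain.
    """
    m = (env.time_axis >= window[0]) & (env.time_axis <= window[1])
    t = env.time_axis[m]
    y = env.values[m]
    b, a = np.polyfit(t, y, 1)
    value_at_onset = a + b * onset
    return float(b / value_at_onset)


def envelope_long_table(envelopes: dict[str, EnvelopeSeries],
                        groups: dict[str, str],
                        window: tuple[float, float] = (0.3, 1.0)
                        ) -> pd.DataFrame:
    """Stack per-subject envelopes into the long table the LME consumes.

    One row per subject per 50 ms bin with center inside ``window``
    (14 bins for 0.3–1.0 s); ``time_ms`` holds bin centers in ms.
    """
    rows = []
    for sid, env in envelopes.items():
        m = (env.time_axis >= window[0]) & (env.time_axis <= window[1])
        for tc, v in zip(env.time_axis[m], env.values[m]):
            rows.append((sid, groups[sid], 1000.0 * tc, float(v)))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "time_ms", "relative_power"])
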