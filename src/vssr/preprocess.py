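"""Preprocessing: high-pass filtering, SSP, epoching, artifact rejection.

The stage order is filter → project → epoch → reject, and each step
appends to the data's provenance list so downstream stages can verify
what they received.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .simulate import Recording

__all__ = [
    "Epochs",
    "RejectionThresholds",
    "highpass_filter",
    "ssp_project",
    "epoch_recording",
    "reject_artifacts",
    "T_PER_M_TO_FT_PER_CM",
]

logger = logging.getLogger(__name__)

#: 1 T/m = 1e15 fT / 100 cm
T_PER_M_TO_FT_PER_CM = 1e13


@dataclass
class Epochs:
    """Epoched gradiometer data: trials × channels × samples."""

    data: np.ndarray
    time_axis: np.ndarray            # s relative to stimulus onset
    sampling_rate: float
    retained_trial_ids: list[int]
    rejection_log: list[dict] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class RejectionThresholds:
    """Per-subject rejection bounds (internal units: T/m, T/m per ms)."""

    amplitude_threshold: float
    gradient_threshold: float

    def __post_init__(self):
        if self.amplitude_threshold <= 0 or self.gradient_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def amplitude_ft_per_cm(self) -> float:
        return self.amplitude_threshold * T_PER_M_TO_FT_PER_CM

    @property
    def gradient_ft_per_cm_ms(self) -> float:
        return self.gradient_threshold * T_PER_M_TO_FT_PER_CM


def highpass_filter(recording: Recording, cutoff: float = 0.3,
                    numtaps: int = 4001) -> Recording:
    """Zero-phase FIR high-pass; removes DC, preserves length.

    A symmetric (linear-phase) FIR applied with a centered convolution
    is exactly zero-phase, so entrainment onset timing is not shifted.
    The kernel is the spectral complement of a unit-DC-gain low-pass
    (δ − lowpass), which nulls DC exactly even though the kernel is
    short relative to the cutoff period.  Edges are reflection-padded
    before convolving.
    """
    fs = recording.sampling_rate
    if cutoff >= fs / 2:
        raise ValueError("cutoff at or above Nyquist")
    from scipy import fft as sfft
    b = -signal.firwin(numtaps, cutoff, pass_zero=True, fs=fs)
    b[(numtaps - 1) // 2] += 1.0
    half = (numtaps - 1) // 2
    padded = np.pad(recording.data, ((0, 0), (half, half)), mode="reflect")
    nfast = sfft.next_fast_len(padded.shape[1] + numtaps - 1, real=True)
    Y = sfft.rfft(padded, n=nfast, axis=1) * sfft.rfft(b, n=nfast)
    full = sfft.irfft(Y, n=nfast, axis=1)
    # centered ("same"-mode) slice of the linear convolution
    out = full[:, numtaps - 1: numtaps - 1 + recording.data.shape[1]]
    return replace(recording, data=out,
                   provenance=recording.provenance
                   + [f"highpass(cutoff={cutoff})"])


def ssp_project(recording: Recording,
                projector_vectors: np.ndarray | None) -> Recording:
    """Remove the span of ``projector_vectors`` from channel space.

    Vectors (channels × k) are orthonormalized internally; the data are
    replaced by ``(I - U Uᵀ) · data``.  The projection is recorded in
    provenance so source imaging can account for the rank reduction.
    An empty projector set is the identity.
    """
    n_ch = recording.data.shape[0]
    if projector_vectors is None or np.size(projector_vectors) == 0:
        return replace(recording,
                       provenance=recording.provenance + ["ssp(k=0)"])
    V = np.atleast_2d(np.asarray(projector_vectors, dtype=float))
    if V.shape[0] != n_ch:
        V = V.T
    k = V.shape[1]
    if k >= n_ch:
        raise ValueError("projector count must be below channel count")
    U, _ = np.linalg.qr(V)
    out = recording.data - U @ (U.T @ recording.data)
    return replace(recording, data=out,
                   provenance=recording.provenance + [f"ssp(k={k})"])


def epoch_recording(recording: Recording,
                    window: tuple[float, float] = (-0.9, 2.0)) -> Epochs:
    """Cut one epoch per stimulus event, time 0 at the event sample.

    Events too close to a recording edge are dropped with a logged
    reason rather than raising.
    """
    if recording.events.shape[0] == 0:
        raise ValueError("recording has no events")
    fs = recording.sampling_rate
    i0 = int(round(window[0] * fs))
    n_samp = int(round((window[1] - window[0]) * fs))
    time_axis = window[0] + np.arange(n_samp) / fs
    n_total = recording.data.shape[1]
    trials, kept, log = [], [], []
    for ti, (sample, _code) in enumerate(recording.events):
        start = int(sample) + i0
        stop = start + n_samp
        if start < 0 or stop > n_total:
            log.append({"trial_id": ti, "decision": "dropped",
                        "reason": "event too close to recording edge"})
            logger.info("trial %d dropped: outside recording", ti)
            continue
        trials.append(recording.data[:, start:stop])
        kept.append(ti)
    if not trials:
        raise ValueError("no event fits the epoch window")
    return Epochs(np.stack(trials), time_axis, fs, kept,
                  rejection_log=log,
                  provenance=recording.provenance
                  + [f"epoch(window={window})"])


def _robust_threshold(peaks: np.ndarray, n_scales: float) -> float:
    """Median + n · (MAD-based SD), floored at the median.

    A resistant location/scale rule: the very artifacts being screened
    for would otherwise inflate a mean/SD rule toward their own level.
    Degenerate (zero-spread) distributions collapse to the median, and
    rejection uses a strict inequality, so identical clean trials are
    all retained.
    """
    med = float(np.median(peaks))
    mad_sd = 1.4826 * float(np.median(np.abs(peaks - med)))
    return max(med + n_scales * mad_sd, med)


def reject_artifacts(epochs: Epochs, n_scales: float = 3.0
                     ) -> tuple[Epochs, RejectionThresholds, int]:
    """Individualized amplitude/gradient threshold rejection.

    Per-trial peak |amplitude| and peak |gradient| (first difference
    per ms) are computed across all channels; thresholds are set from
    each statistic's own distribution over trials, and any trial
    strictly exceeding either threshold is removed.
    """
    if epochs.n_trials < 10:
        raise ValueError("need at least 10 trials to set thresholds")
    ms_per_sample = 1000.0 / epochs.sampling_rate
    peak_amp = np.abs(epochs.data).max(axis=(1, 2))
    grad = np.abs(np.diff(epochs.data, axis=2)) / ms_per_sample
    peak_grad = grad.max(axis=(1, 2))

    th = RejectionThresholds(
        _robust_threshold(peak_amp, n_scales),
        _robust_threshold(peak_grad, n_scales))
    keep = ((peak_amp <= th.amplitude_threshold)
            & (peak_grad <= th.gradient_threshold))
    if not keep.any():
        raise ValueError(
            "all trials rejected — review thresholds "
            f"(amp={th.amplitude_ft_per_cm:.1f} fT/cm, "
            f"grad={th.gradient_ft_per_cm_ms:.1f} fT/(cm·ms))")

    log = list(epochs.rejection_log)
    for i, trial_id in enumerate(epochs.retained_trial_ids):
        log.append({
            "trial_id": trial_id,
            "peak_amp": float(peak_amp[i]),
            "peak_grad": float(peak_grad[i]),
            "decision": "retained" if keep[i] else "rejected",
        })
    n_retained = int(keep.sum())
    logger.info("retained %d/%d trials (amp thresh %.1f fT/cm, "
                "grad thresh %.1f fT/(cm·ms))", n_retained, epochs.n_trials,
                th.amplitude_ft_per_cm, th.gradient_ft_per_cm_ms)
    out = Epochs(epochs.data[keep], epochs.time_axis, epochs.sampling_rate,
                 [tid for i, tid in enumerate(epochs.retained_trial_ids)
                  if keep[i]],
                 rejection_log=log,
                 provenance=epochs.provenance + ["reject_artifacts"])
    return out, th, n_retained
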