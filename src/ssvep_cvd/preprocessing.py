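"""EEG signal conditioning: filtering, re-referencing, segmentation,
amplitude-based artifact rejection, and per-session trial averaging.

The canonical chain for this paradigm is

    band-pass 5-30 Hz -> notch 60 Hz -> (band-pass 5-50 Hz) ->
    average re-reference -> trigger segmentation into 10-s trials ->
    reject trials exceeding +/-100 µV on any channel ->
    average the surviving trials of each session.

Filters default to zero-phase (forward-backward) application so trial
boundaries are not smeared by group delay; a causal single-pass mode is
available to replicate a strict Nth-order online filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io_recording import REST, STIMULATION, Recording, epochs_from_trigger

AGGREGATE_TRIAL = 0  #: trial_index marking a cross-trial average


@dataclass
class TrialSegment:
    """One fixed-length epoch of conditioned EEG (channels x samples, µV)."""

    data: np.ndarray
    session_id: int
    trial_index: int  # 1-based; AGGREGATE_TRIAL for session averages
    label: str
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.label not in (STIMULATION, REST):
            raise ValueError(f"unknown segment label {self.label!r}")


def _apply_sos(rec: Recording, sos: np.ndarray, zero_phase: bool) -> Recording:
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    out = rec.copy()
    out.data = np.ascontiguousarray(filt(sos, rec.data, axis=1))
    return out


def bandpass_filter(
    rec: Recording,
    low: float = 5.0,
    high: float = 30.0,
    order: int = 4,
    zero_phase: bool = True,
) -> Recording:
    """Butterworth band-pass; returns a new Recording, trigger untouched."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return _apply_sos(rec, sos, zero_phase)


def notch_filter(
    rec: Recording, f0: float = 60.0, q: float = 30.0, zero_phase: bool = True
) -> Recording:
    """IIR notch at *f0* (power-line removal); trigger untouched."""
    if not (0 < f0 < rec.fs / 2):
        raise ValueError(f"notch frequency {f0} Hz outside (0, {rec.fs / 2}) Hz")
    b, a = signal.iirnotch(f0, q, fs=rec.fs)
    out = rec.copy()
    filt = signal.filtfilt if zero_phase else signal.lfilter
    out.data = np.ascontiguousarray(filt(b, a, rec.data, axis=1))
    return out


def rereference_average(rec: Recording) -> Recording:
    """Subtract the across-channel mean at every sample (common average)."""
    if rec.n_channels < 2:
        raise ValueError("average re-reference needs at least 2 channels")
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return out


def preprocess_recording(
    rec: Recording,
    bands: tuple[tuple[float, float], ...] = ((5.0, 30.0), (5.0, 50.0)),
    notch_hz: float | None = 60.0,
    order: int = 4,
    zero_phase: bool = True,
) -> Recording:
    """The full conditioning chain up to (not including) segmentation.

    Applies the first band-pass, the notch, any further band-pass stages in
    order, then the average re-reference. With the defaults the second
    5-50 Hz stage is spectrally redundant after 5-30 Hz but retained for
    chain fidelity; pass ``bands=((5, 30),)`` to collapse it.
    """
    out = rec
    for i, (low, high) in enumerate(bands):
        out = bandpass_filter(out, low, high, order=order, zero_phase=zero_phase)
        if i == 0 and notch_hz is not None:
            out = notch_filter(out, notch_hz, zero_phase=zero_phase)
    return rereference_average(out)


def segment_trials(
    rec: Recording,
    trial_s: float = 10.0,
    n_trials_per_session: int = 10,
    include_rest: bool = False,
    tolerance_samples: int = 2,
) -> list[TrialSegment]:
    """Cut the recording into fixed-length trials using the trigger.

    Consecutive blocks of *n_trials_per_session* stimulation epochs map to
    sessions 1, 2, ... (the sequential protocol). Epochs within
    *tolerance_samples* of the nominal length are trimmed or zero-padded to
    exactly ``trial_s * fs`` samples; shorter epochs are skipped with a
    warning.
    """
    n_target = int(round(trial_s * rec.fs))
    segments: list[TrialSegment] = []
    counters = {STIMULATION: 0, REST: 0}
    for epoch in epochs_from_trigger(rec):
        if not include_rest and epoch.label == REST:
            continue
        data = rec.data[:, epoch.start : epoch.end]
        if data.shape[1] < n_target - tolerance_samples:
            warnings.warn(
                f"skipping {epoch.label} epoch [{epoch.start}, {epoch.end}): "
                f"{data.shape[1]} samples < nominal {n_target}",
                stacklevel=2,
            )
            continue
        if data.shape[1] > n_target:
            data = data[:, :n_target]
        elif data.shape[1] < n_target:
            pad = n_target - data.shape[1]
            data = np.pad(data, ((0, 0), (0, pad)))
        k = counters[epoch.label]
        counters[epoch.label] += 1
        segments.append(
            TrialSegment(
                data=data.copy(),
                session_id=k // n_trials_per_session + 1,
                trial_index=k % n_trials_per_session + 1,
                label=epoch.label,
                fs=rec.fs,
            )
        )
    return segments


def reject_amplitude(
    segments: list[TrialSegment], threshold: float = 100.0
) -> tuple[list[TrialSegment], list[TrialSegment]]:
    """Partition segments: rejected iff any channel sample exceeds ±threshold µV.

    The bound is inclusive — a sample at exactly ±threshold is kept.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    kept, rejected = [], []
    for seg in segments:
        (rejected if np.max(np.abs(seg.data)) > threshold else kept).append(seg)
    return kept, rejected


def average_trials(segments: list[TrialSegment]) -> TrialSegment:
    """Element-wise mean of one session's trials (SNR improvement step)."""
    if not segments:
        raise ValueError("session unusable: no surviving trials to average")
    shapes = {seg.data.shape for seg in segments}
    if len(shapes) > 1:
        raise ValueError(f"segments have differing shapes: {sorted(shapes)}")
    first = segments[0]
    return TrialSegment(
        data=np.mean([seg.data for seg in segments], axis=0),
        session_id=first.session_id,
        trial_index=AGGREGATE_TRIAL,
        label=first.label,
        fs=first.fs,
    )


def session_averages(
    segments: list[TrialSegment], label: str = STIMULATION
) -> dict[int, TrialSegment]:
    """Per-session averaged stimulation (or rest) segments, keyed by session."""
    by_session: dict[int, list[TrialSegment]] = {}
    for seg in segments:
        if seg.label == label:
            by_session.setdefault(seg.session_id, []).append(seg)
    return {sid: average_trials(segs) for sid, segs in sorted(by_session.items())}
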