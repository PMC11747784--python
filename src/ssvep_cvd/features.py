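"""Spectral and canonical-correlation features for SSVEP decoding.

Two detection statistics are extracted at each candidate stimulation
frequency (15 and 18 Hz) on each channel (O1, O2, Pz, Cz):

* the Welch power spectral density at the frequency's bin, in µV²/Hz —
  segment periodograms (Hann window, 50% overlap, mean-detrended) averaged
  over the trial;
* the maximum canonical correlation between the channel and a sine/cosine
  harmonic reference bank at the candidate frequency. For a single channel
  the maximum canonical correlation reduces to the multiple correlation
  coefficient of the channel on the reference rows, computed here via the
  reference-side normal equations with a tiny ridge for rank safety.

The per-subject feature vector is the canonical 16-element layout
``[PSD(ch, 15) x4, PSD(ch, 18) x4, CCA(ch, 15) x4, CCA(ch, 18) x4]`` with
channels ordered O1, O2, Pz, Cz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import TrialSegment

FEATURE_CHANNELS = ("O1", "O2", "Pz", "Cz")
FEATURE_FREQS = (15.0, 18.0)


def feature_names(
    channels: tuple[str, ...] = FEATURE_CHANNELS,
    freqs: tuple[float, ...] = FEATURE_FREQS,
) -> list[str]:
    """Canonical column names: all PSD features, then all CCA features."""
    names = []
    for kind in ("psd", "cca"):
        for f in freqs:
            for ch in channels:
                names.append(f"{kind}_{ch}_{f:g}Hz")
    return names


@dataclass
class SpectralEstimate:
    """A one-sided Welch PSD estimate (channels x frequency bins)."""

    freqs: np.ndarray
    psd: np.ndarray  # µV²/Hz
    nperseg: int
    n_segments: int
    window: str = "hann"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))


@dataclass
class ReferenceSet:
    """Sine/cosine harmonic bank at a candidate stimulation frequency.

    ``matrix`` rows alternate sin/cos for harmonics 1..H sampled at
    t = m/fs: [sin(2πft), cos(2πft), ..., sin(2πHft), cos(2πHft)].
    """

    frequency: float
    n_harmonics: int
    fs: float
    matrix: np.ndarray


@dataclass
class FeatureVector:
    subject_id: str
    values: np.ndarray  # 16 ordered reals per feature_names()
    label: str = "unknown"  # "normal" | "cvd" | "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def hann_window(m: int) -> np.ndarray:
    """Periodic Hann window of length m (the DFT-analysis convention)."""
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(m) / m)


def periodogram_segment(
    x: np.ndarray,
    fs: float = 250.0,
    window: np.ndarray | None = None,
    detrend: bool = True,
    density: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram |X(k)|²/M of a single segment.

    With ``density=True`` the estimate is scaled to a spectral density in
    µV²/Hz: divide by fs·Σw² and double every bin except DC (and Nyquist
    for even M), so the one-sided integral equals the signal power. With
    ``density=False`` the unscaled |X(k)|²/M textbook form is returned.
    Each segment is mean-subtracted before windowing when *detrend* is set.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    if m < 2:
        raise ValueError(f"segment must have at least 2 samples, got {m}")
    if window is None:
        window = np.ones(m)
    if window.size != m:
        raise ValueError("window length must match segment length")
    if detrend:
        x = x - x.mean()
    spec = np.fft.rfft(x * window)
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    p = np.abs(spec) ** 2
    if density:
        p = p / (fs * np.sum(window**2))
        one_sided = np.full(p.size, 2.0)
        one_sided[0] = 1.0
        if m % 2 == 0:
            one_sided[-1] = 1.0
        p = p * one_sided
    else:
        p = p / m
    return freqs, p


def segment_starts(n: int, nperseg: int, overlap: float) -> np.ndarray:
    """Start indices of the Welch segment decomposition."""
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    step = int(round(nperseg * (1 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: step underflows to zero")
    return np.arange(0, n - nperseg + 1, step)


def welch_psd(
    x: np.ndarray,
    fs: float = 250.0,
    nperseg: int = 250,
    overlap: float = 0.5,
    window: str = "hann",
    density: bool = True,
) -> SpectralEstimate:
    """Welch PSD: the mean of the windowed segment periodograms.

    At the defaults a 2,500-sample (10 s) trial decomposes into 19 segments
    of 250 samples with 50% overlap, giving 1 Hz frequency resolution so the
    15 and 18 Hz stimulation frequencies fall exactly on bins. Accepts a
    single channel (1-D) or a channels x samples matrix.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    if nperseg > n:
        raise ValueError(f"nperseg={nperseg} exceeds signal length {n}")
    if window == "hann":
        w = hann_window(nperseg)
    elif window in ("boxcar", "rectangular", None):
        w = np.ones(nperseg)
    else:
        raise ValueError(f"unsupported window {window!r}")
    starts = segment_starts(n, nperseg, overlap)
    psd = None
    for s in starts:
        seg_p = np.stack(
            [
                periodogram_segment(row[s : s + nperseg], fs, w, density=density)[1]
                for row in x
            ]
        )
        psd = seg_p if psd is None else psd + seg_p
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return SpectralEstimate(
        freqs=freqs,
        psd=psd / len(starts),
        nperseg=nperseg,
        n_segments=len(starts),
        window=window if window else "boxcar",
    )


def psd_feature(spec: SpectralEstimate, f: float, channel: int = 0) -> float:
    """PSD at the bin nearest *f*; ties break toward the lower frequency."""
    if not (spec.freqs[0] <= f <= spec.freqs[-1]):
        raise ValueError(
            f"frequency {f} Hz outside spectrum range "
            f"[{spec.freqs[0]}, {spec.freqs[-1]}] Hz"
        )
    # argmin returns the first (lowest-frequency) minimizer, which is the tie rule
    k = int(np.argmin(np.abs(spec.freqs - f)))
    return float(spec.psd[channel, k])


def build_reference(
    f: float, n_harmonics: int = 3, fs: float = 250.0, n: int = 2500
) -> ReferenceSet:
    """Sine/cosine reference bank for harmonics 1..H of *f* (2H rows)."""
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    for h in range(1, n_harmonics + 1):
        if h * f >= fs / 2:
            raise ValueError(
                f"harmonic {h} of {f} Hz ({h * f} Hz) is at or above Nyquist ({fs / 2} Hz)"
            )
    t = np.arange(n) / fs
    rows = []
    for h in range(1, n_harmonics + 1):
        rows.append(np.sin(2 * np.pi * h * f * t))
        rows.append(np.cos(2 * np.pi * h * f * t))
    return ReferenceSet(
        frequency=f, n_harmonics=n_harmonics, fs=fs, matrix=np.stack(rows)
    )


def cca_max_correlation(
    x: np.ndarray, ref: ReferenceSet, ridge: float = 1e-10
) -> float:
    """Maximum canonical correlation between channel *x* and the reference.

    For one-dimensional x this is the multiple correlation coefficient:
    rho² = c' G⁻¹ c / (x'x) with c = Y x and G = Y Y' over centered data.
    A ridge of ``ridge * trace(G)/2H`` guards near-singular references.
    Returns a value clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = ref.matrix
    if x.size != y.shape[1]:
        raise ValueError(
            f"signal length {x.size} != reference length {y.shape[1]}"
        )
    xc = x - x.mean()
    ss_x = float(xc @ xc)
    if ss_x <= 0:
        raise ValueError("correlation undefined for a constant signal")
    yc = y - y.mean(axis=1, keepdims=True)
    gram = yc @ yc.T
    gram = gram + ridge * (np.trace(gram) / gram.shape[0]) * np.eye(gram.shape[0])
    c = yc @ xc
    rho_sq = float(c @ np.linalg.solve(gram, c)) / ss_x
    return float(np.clip(np.sqrt(max(rho_sq, 0.0)), 0.0, 1.0))


def cca_max_correlation_multichannel(
    x: np.ndarray, ref: ReferenceSet, ridge: float = 1e-10
) -> float:
    """Max canonical correlation between a channels x samples block and the
    reference bank (the classical multiset CCA used for exploration)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = ref.matrix - ref.matrix.mean(axis=1, keepdims=True)
    cxx = xc @ xc.T
    cyy = yc @ yc.T
    cxy = xc @ yc.T
    cxx += ridge * (np.trace(cxx) / cxx.shape[0]) * np.eye(cxx.shape[0])
    cyy += ridge * (np.trace(cyy) / cyy.shape[0]) * np.eye(cyy.shape[0])
    m = np.linalg.solve(cxx, cxy) @ np.linalg.solve(cyy, cxy.T)
    eigvals = np.linalg.eigvals(m).real
    return float(np.clip(np.sqrt(max(eigvals.max(), 0.0)), 0.0, 1.0))


def extract_feature_vector(
    segments_by_freq: dict[float, TrialSegment],
    channel_names: tuple[str, ...],
    subject_id: str = "",
    label: str = "unknown",
    freqs: tuple[float, ...] = FEATURE_FREQS,
    n_harmonics: int = 3,
    nperseg: int = 250,
    overlap: float = 0.5,
) -> FeatureVector:
    """Assemble the canonical 16-element feature vector for one subject.

    *segments_by_freq* maps each candidate frequency to the averaged
    stimulation segment of the sessions where that frequency tagged the
    target plate; the PSD and CCA features at a frequency are measured on
    that frequency's segment. Channels are re-ordered to the canonical
    O1, O2, Pz, Cz layout regardless of input order.
    """
    missing = [f for f in freqs if f not in segments_by_freq]
    if missing:
        raise ValueError(f"no averaged segment for frequencies {missing}")
    ch_index = {}
    for ch in FEATURE_CHANNELS:
        if ch not in channel_names:
            raise ValueError(f"required channel {ch!r} missing from {channel_names}")
        ch_index[ch] = channel_names.index(ch)

    psd_vals, cca_vals = [], []
    for f in freqs:
        seg = segments_by_freq[f]
        spec = welch_psd(seg.data, fs=seg.fs, nperseg=nperseg, overlap=overlap)
        ref = build_reference(f, n_harmonics, seg.fs, seg.data.shape[1])
        for ch in FEATURE_CHANNELS:
            psd_vals.append(psd_feature(spec, f, channel=ch_index[ch]))
        for ch in FEATURE_CHANNELS:
            cca_vals.append(cca_max_correlation(seg.data[ch_index[ch]], ref))
    return FeatureVector(
        subject_id=subject_id, values=np.array(psd_vals + cca_vals), label=label
    )


def psd_group_ratio(
    spec_normal: SpectralEstimate,
    spec_cvd: SpectralEstimate,
    band: tuple[float, float],
    channel: int = 0,
) -> float:
    """Normal-group mean PSD over *band* divided by the CVD-group mean.

    Ratios above 1 mean the normal-vision group carries more power in the
    band; below 1, the CVD group does.
    """
    if not np.allclose(spec_normal.freqs, spec_cvd.freqs):
        raise ValueError("spectra must share a frequency grid")
    lo, hi = band
    mask = (spec_normal.freqs >= lo) & (spec_normal.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    num = float(spec_normal.psd[channel, mask].mean())
    den = float(spec_cvd.psd[channel, mask].mean())
    if den == 0:
        raise ZeroDivisionError("CVD-group PSD is zero over the band")
    return num / den
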