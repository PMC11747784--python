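"""Synthetic SSVEP cohort generator.

Emulates the frequency-tagged Ishihara-plate paradigm: each subject sits
six sessions of ten 10-s stimulation trials (10-s rests in between), in each
session attending one of two squares flickering at 15 or 18 Hz. A plate pair
sits above the squares; which plate a subject picks — and hence which
frequency entrains their visual cortex — depends on their color vision:
normal-vision subjects pick the target plate, red-green CVD subjects the
non-target plate (including hidden-digit plates only they can read).

The EEG model per channel is a sum of:

* an SSVEP at the attended frequency and its harmonics, phase-locked within
  a session (stimulus-onset-locked, so trial averaging gains SNR), strongest
  at O1/O2, weaker at Pz, weakest at Cz;
* a ~10 Hz non-target alpha/display tone;
* 1/f (pink) background noise;
* 60 Hz line noise;
* sparse high-amplitude artifact transients (blink-like pulses).

All randomness flows through numpy Generators derived from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_recording import DEFAULT_CHANNELS, Recording

FREQ_PAIR = (15.0, 18.0)

#: Per-session question digits and hidden-digit layout of the plate table:
#: sessions ask for "2", "45", "5", "5", "5", "2"; in sessions 2, 4 and 6 the
#: non-target plate is a hidden-digit plate (readable only with CVD).
_SESSION_DIGITS = ("2", "45", "5", "5", "5", "2")
_HIDDEN_SESSIONS = (2, 4, 6)


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth behavioral profile of a simulated subject."""

    subject_id: str
    condition: str  # "normal" | "cvd"
    severity: float = 1.0  # P(recognize a hidden digit); CVD only
    lapse_rate: float = 0.0  # P(uniformly random choice in a session)

    def __post_init__(self) -> None:
        if self.condition not in ("normal", "cvd"):
            raise ValueError(f"condition must be 'normal' or 'cvd', got {self.condition!r}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError(f"lapse_rate must be in [0, 1], got {self.lapse_rate}")


@dataclass(frozen=True)
class SessionPlan:
    """One session's plate pair and frequency tagging."""

    session_id: int  # 1..6
    question_digit: str
    target_frequency: float
    nontarget_frequency: float
    target_plate_is_hidden_digit: bool = False
    nontarget_plate_is_hidden_digit: bool = False

    def __post_init__(self) -> None:
        if {self.target_frequency, self.nontarget_frequency} != set(FREQ_PAIR):
            raise ValueError(
                f"session {self.session_id}: frequency pair must be {FREQ_PAIR}, got "
                f"({self.target_frequency}, {self.nontarget_frequency})"
            )


@dataclass
class SimConfig:
    """Generator parameters (amplitudes in µV, durations in s, rates in Hz)."""

    fs: float = 250.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    trial_s: float = 10.0
    rest_s: float = 10.0
    n_trials_per_session: int = 10
    n_sessions: int = 6
    #: SSVEP fundamental amplitude per channel; occipital-dominant topography
    ssvep_amp: dict = field(
        default_factory=lambda: {"O1": 2.0, "O2": 2.0, "Pz": 1.0, "Cz": 0.5}
    )
    harmonic_decay: float = 0.5
    n_harmonics_gen: int = 3
    alpha_freq: float = 10.0
    alpha_amp: float = 2.0
    noise_scale: float = 5.0  # RMS of the 1/f process
    noise_exponent: float = 1.0
    line_freq: float = 60.0
    line_amp: float = 1.0
    artifact_rate: float = 0.5  # artifacts per minute
    artifact_amp: float = 150.0
    artifact_width_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("alpha_amp", "noise_scale", "line_amp", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(a < 0 for a in self.ssvep_amp.values()):
            raise ValueError("ssvep_amp values must be non-negative")
        if not (0 < self.harmonic_decay <= 1):
            raise ValueError("harmonic_decay must lie in (0, 1]")
        n = self.trial_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_s * fs must be an integer sample count")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_s * self.fs))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_s * self.fs))


def default_session_plans(
    target_freq_odd: float = 15.0, target_freq_even: float = 18.0
) -> list[SessionPlan]:
    """The six-session plate table with the default frequency tagging.

    The target plate's square flickers at 15 Hz in odd sessions and 18 Hz in
    even sessions (overridable), so both frequencies serve as target in three
    sessions each.
    """
    plans = []
    for sid, digit in enumerate(_SESSION_DIGITS, start=1):
        target = target_freq_odd if sid % 2 == 1 else target_freq_even
        nontarget = FREQ_PAIR[0] if target == FREQ_PAIR[1] else FREQ_PAIR[1]
        plans.append(
            SessionPlan(
                session_id=sid,
                question_digit=digit,
                target_frequency=target,
                nontarget_frequency=nontarget,
                nontarget_plate_is_hidden_digit=sid in _HIDDEN_SESSIONS,
            )
        )
    return plans


def simulate_choice(
    profile: SubjectProfile, plan: SessionPlan, rng: np.random.Generator
) -> float:
    """Which frequency the subject attends in this session.

    With probability ``lapse_rate`` the choice is uniformly random.
    Otherwise: normal vision picks the target plate; CVD picks the
    non-target plate — for a hidden-digit non-target, only with probability
    ``severity`` (a mild deficiency may not resolve the hidden digit, in
    which case the subject falls back to the target plate).
    """
    if rng.random() < profile.lapse_rate:
        return float(rng.choice([plan.target_frequency, plan.nontarget_frequency]))
    if profile.condition == "normal":
        return plan.target_frequency
    if plan.nontarget_plate_is_hidden_digit:
        if rng.random() < profile.severity:
            return plan.nontarget_frequency
        return plan.target_frequency
    return plan.nontarget_frequency


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _background(
    n: int, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-channel alpha + pink noise + line noise + sparse artifacts."""
    t = np.arange(n) / cfg.fs
    out = np.empty((len(cfg.channel_names), n))
    for ch in range(len(cfg.channel_names)):
        x = cfg.alpha_amp * np.sin(
            2 * np.pi * cfg.alpha_freq * t + rng.uniform(0, 2 * np.pi)
        )
        if cfg.noise_scale > 0:
            x = x + cfg.noise_scale * _pink_noise(n, cfg.noise_exponent, rng)
        if cfg.line_amp > 0:
            x = x + cfg.line_amp * np.sin(
                2 * np.pi * cfg.line_freq * t + rng.uniform(0, 2 * np.pi)
            )
        out[ch] = x
    # blink-like transient hitting all channels at once
    p_artifact = cfg.artifact_rate * (n / cfg.fs) / 60.0
    if cfg.artifact_amp > 0 and rng.random() < p_artifact:
        width = max(2, int(round(cfg.artifact_width_s * cfg.fs)))
        start = int(rng.integers(0, max(1, n - width)))
        pulse = np.hanning(width) * cfg.artifact_amp * rng.choice([-1.0, 1.0])
        out[:, start : start + width] += pulse[: n - start]
    return out


def synthesize_trial(
    attended_freq: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    ssvep_phases: np.ndarray | None = None,
) -> np.ndarray:
    """One 10-s stimulation trial, channels x samples, µV.

    *ssvep_phases* (channels x generated harmonics) lets the caller
    phase-lock the evoked response across a session's trials; when omitted,
    phases are drawn from *rng*. Phases vary across channels (cortical
    propagation delays), which also keeps the average re-reference from
    cancelling a common-mode evoked component. Harmonics at or above
    Nyquist are skipped.
    """
    n = cfg.trial_samples
    t = np.arange(n) / cfg.fs
    if ssvep_phases is None:
        ssvep_phases = rng.uniform(
            0, 2 * np.pi, size=(len(cfg.channel_names), cfg.n_harmonics_gen)
        )
    ssvep_phases = np.atleast_2d(ssvep_phases)
    if ssvep_phases.shape[0] == 1:
        ssvep_phases = np.broadcast_to(
            ssvep_phases, (len(cfg.channel_names), cfg.n_harmonics_gen)
        )
    out = _background(n, cfg, rng)
    for ch_idx, ch_name in enumerate(cfg.channel_names):
        amp = cfg.ssvep_amp.get(ch_name, 0.0)
        if amp == 0.0:
            continue
        for h in range(1, cfg.n_harmonics_gen + 1):
            f_h = h * attended_freq
            if f_h >= cfg.fs / 2:
                continue
            out[ch_idx] += (
                amp
                * cfg.harmonic_decay ** (h - 1)
                * np.sin(2 * np.pi * f_h * t + ssvep_phases[ch_idx, h - 1])
            )
    return out


def simulate_recording(
    profile: SubjectProfile,
    cfg: SimConfig,
    plans: list[SessionPlan],
    rng: np.random.Generator,
) -> Recording:
    """One subject's full recording: sessions x (trial + rest) epochs."""
    blocks: list[np.ndarray] = []
    trig: list[np.ndarray] = []
    attended: list[float] = []
    for plan in plans[: cfg.n_sessions]:
        freq = simulate_choice(profile, plan, rng)
        attended.append(freq)
        phases = rng.uniform(
            0, 2 * np.pi, size=(len(cfg.channel_names), cfg.n_harmonics_gen)
        )
        for _ in range(cfg.n_trials_per_session):
            blocks.append(synthesize_trial(freq, cfg, rng, ssvep_phases=phases))
            trig.append(np.zeros(cfg.trial_samples, dtype=int))
            blocks.append(_background(cfg.rest_samples, cfg, rng))
            trig.append(np.ones(cfg.rest_samples, dtype=int))
    return Recording(
        data=np.concatenate(blocks, axis=1),
        trigger=np.concatenate(trig),
        fs=cfg.fs,
        channel_names=cfg.channel_names,
        meta={
            "subject_id": profile.subject_id,
            "condition": profile.condition,
            "attended_frequencies": ",".join(f"{f:g}" for f in attended),
        },
    )


def simulate_cohort(
    n_normal: int,
    n_cvd: int,
    cfg: SimConfig | None = None,
    plans: list[SessionPlan] | None = None,
    seed: int | None = None,
    severity: float = 1.0,
    lapse_rate: float = 0.0,
) -> list[tuple[Recording, SubjectProfile]]:
    """Simulate a cohort; the study-shaped default is 11 normal + 5 CVD.

    Each subject gets an independent random stream spawned from *seed*
    (falling back to ``cfg.seed``), so the cohort is reproducible and
    insensitive to subject order.
    """
    if n_normal < 0 or n_cvd < 0:
        raise ValueError("cohort counts must be non-negative")
    cfg = cfg if cfg is not None else SimConfig()
    plans = plans if plans is not None else default_session_plans()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    profiles = [
        SubjectProfile(f"N{i + 1:02d}", "normal", lapse_rate=lapse_rate)
        for i in range(n_normal)
    ] + [
        SubjectProfile(f"C{i + 1:02d}", "cvd", severity=severity, lapse_rate=lapse_rate)
        for i in range(n_cvd)
    ]
    out = []
    for profile, child in zip(profiles, root.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        out.append((simulate_recording(profile, cfg, plans, rng), profile))
    return out
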