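"""Rule-based paradigm inference: attended frequency per session, plate
choice, comparison against the plate-table expectations, and a subject-level
CVD call with a hidden-digit severity score.

This path makes the paradigm logic testable on its own; the machine-learning
classifier (the :mod:`.ml` module) is the companion route, not a competitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    build_reference,
    cca_max_correlation,
    psd_feature,
    welch_psd,
)
from .preprocessing import TrialSegment
from .synthetic_data import SessionPlan

TARGET = "target"
NONTARGET = "nontarget"


@dataclass
class SessionResult:
    session_id: int
    detected_frequency: float
    score_15: float
    score_18: float
    chosen_plate: str  # "target" | "nontarget"
    matches_cvd_expectation: bool
    nontarget_is_hidden: bool = False
    indeterminate: bool = False


@dataclass
class DiagnosisResult:
    subject_id: str
    session_results: list[SessionResult]
    n_cvd_matches: int
    call: str  # "normal" | "cvd" | "indeterminate"
    severity_score: int  # hidden-digit plates chosen among the hidden sessions


def _method_scores(
    avg_segment: TrialSegment,
    freqs: tuple[float, float],
    method: str,
    n_harmonics: int = 3,
    nperseg: int = 250,
    overlap: float = 0.5,
) -> dict[float, float]:
    data = avg_segment.data
    n_ch = data.shape[0]
    scores: dict[float, float] = {}
    if method in ("psd", "fused"):
        spec = welch_psd(data, fs=avg_segment.fs, nperseg=nperseg, overlap=overlap)
        psd_scores = {
            f: float(np.mean([psd_feature(spec, f, channel=c) for c in range(n_ch)]))
            for f in freqs
        }
    if method in ("cca", "fused"):
        cca_scores = {}
        for f in freqs:
            ref = build_reference(f, n_harmonics, avg_segment.fs, data.shape[1])
            cca_scores[f] = float(
                np.mean([cca_max_correlation(data[c], ref) for c in range(n_ch)])
            )
    if method == "psd":
        scores = psd_scores
    elif method == "cca":
        scores = cca_scores
    elif method == "fused":
        # mean of per-method min-max normalized scores (order-preserving)
        scores = {}
        for f in freqs:
            parts = []
            for d in (psd_scores, cca_scores):
                lo, hi = min(d.values()), max(d.values())
                parts.append(0.5 if hi == lo else (d[f] - lo) / (hi - lo))
            scores[f] = float(np.mean(parts))
    else:
        raise ValueError(f"unknown method {method!r}; use psd, cca, or fused")
    return scores


def detect_attended_frequency(
    avg_segment: TrialSegment,
    freqs: tuple[float, float] = (15.0, 18.0),
    method: str = "cca",
    tie_break: float | None = None,
    n_harmonics: int = 3,
) -> tuple[float, float, float]:
    """Decide which candidate frequency the subject attended.

    The score of each candidate is the across-channel mean of the method's
    statistic (Welch PSD at the bin, CCA rho, or their min-max-fused mean);
    the detected frequency is the argmax. An exact tie resolves to
    *tie_break* when given (the caller usually passes the session's target
    frequency, biasing ties toward a normal-vision read), else to the first
    candidate. An all-zero segment yields a NaN-scored indeterminate tuple.

    Returns ``(detected_hz, score_at_freqs[0], score_at_freqs[1])``.
    """
    if not np.any(avg_segment.data):
        return (float("nan"), float("nan"), float("nan"))
    scores = _method_scores(avg_segment, freqs, method, n_harmonics=n_harmonics)
    f0, f1 = freqs
    if scores[f0] == scores[f1]:
        detected = tie_break if tie_break in freqs else f0
    else:
        detected = f0 if scores[f0] > scores[f1] else f1
    return (float(detected), scores[f0], scores[f1])


def score_session(
    detected: float,
    plan: SessionPlan,
    score_15: float = float("nan"),
    score_18: float = float("nan"),
) -> SessionResult:
    """Map a detected frequency to a plate choice and the CVD expectation.

    The plate-table expectation is that normal vision selects the target
    plate and CVD the non-target plate, so ``matches_cvd_expectation`` is
    simply "chose the non-target plate".
    """
    if np.isnan(detected):
        return SessionResult(
            session_id=plan.session_id,
            detected_frequency=float("nan"),
            score_15=score_15,
            score_18=score_18,
            chosen_plate=TARGET,
            matches_cvd_expectation=False,
            nontarget_is_hidden=plan.nontarget_plate_is_hidden_digit,
            indeterminate=True,
        )
    if detected not in (plan.target_frequency, plan.nontarget_frequency):
        raise ValueError(
            f"detected frequency {detected} not in session {plan.session_id}'s pair"
        )
    chosen = TARGET if detected == plan.target_frequency else NONTARGET
    return SessionResult(
        session_id=plan.session_id,
        detected_frequency=float(detected),
        score_15=score_15,
        score_18=score_18,
        chosen_plate=chosen,
        matches_cvd_expectation=(chosen == NONTARGET),
        nontarget_is_hidden=plan.nontarget_plate_is_hidden_digit,
    )


def diagnose_subject(
    session_results: list[SessionResult],
    threshold: int = 4,
    subject_id: str = "",
) -> DiagnosisResult:
    """Subject-level call from the six session results.

    ``cvd`` when at least *threshold* sessions match the CVD expectation,
    ``normal`` when at most ``6 - threshold`` do, ``indeterminate`` in the
    symmetric band between. The severity score counts hidden-digit plates
    actually chosen (0-3 with the default plate table).
    """
    n_sessions = len(session_results)
    if n_sessions != 6:
        raise ValueError(f"expected exactly 6 session results, got {n_sessions}")
    n_matches = sum(r.matches_cvd_expectation for r in session_results)
    if n_matches >= threshold:
        call = "cvd"
    elif n_matches <= n_sessions - threshold:
        call = "normal"
    else:
        call = "indeterminate"
    severity = sum(
        r.nontarget_is_hidden and r.chosen_plate == NONTARGET
        for r in session_results
    )
    return DiagnosisResult(
        subject_id=subject_id,
        session_results=list(session_results),
        n_cvd_matches=n_matches,
        call=call,
        severity_score=severity,
    )


def diagnose_from_averages(
    averages_by_session: dict[int, TrialSegment],
    plans: list[SessionPlan],
    method: str = "cca",
    threshold: int = 4,
    subject_id: str = "",
) -> DiagnosisResult:
    """Full rule-based route: detect each session, score, and call."""
    results = []
    for plan in plans:
        if plan.session_id not in averages_by_session:
            raise ValueError(f"no averaged segment for session {plan.session_id}")
        seg = averages_by_session[plan.session_id]
        detected, s15, s18 = detect_attended_frequency(
            seg, method=method, tie_break=plan.target_frequency
        )
        results.append(score_session(detected, plan, score_15=s15, score_18=s18))
    return diagnose_subject(results, threshold=threshold, subject_id=subject_id)
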