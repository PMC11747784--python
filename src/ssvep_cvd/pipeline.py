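"""End-to-end orchestration: simulate -> preprocess -> features ->
diagnose -> classify, under one seeded configuration.

Every stage is a thin call into the corresponding library module; this
module owns configuration parsing, the subject-level feature assembly that
ties stages together, and the run manifest. Identical config + seed gives
bit-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnosis as dx
from . import features as ft
from . import ml
from . import preprocessing as pp
from . import synthetic_data as sd
from .io_recording import Recording


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the study protocol
    (fs 250 Hz, bands 5-30 then 5-50 Hz, notch 60 Hz, ±100 µV rejection,
    nperseg 250 at 50% overlap, 3 harmonics, 5 folds)."""

    # cohort
    n_normal: int = 11
    n_cvd: int = 5
    severity: float = 1.0
    lapse_rate: float = 0.0
    seed: int = 7
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    # preprocessing
    bands: tuple[tuple[float, float], ...] = ((5.0, 30.0), (5.0, 50.0))
    notch_hz: float = 60.0
    reject_uv: float = 100.0
    # features
    nperseg: int = 250
    overlap: float = 0.5
    n_harmonics: int = 3
    # diagnosis
    method: str = "cca"
    threshold: int = 4
    # classification
    k_folds: int = 5
    smote_mode: str = "fold_internal"
    classifiers: tuple[str, ...] = ("dt", "knn", "svm")
    feature_sets: tuple[str, ...] = ("psd", "cca", "psd+cca")
    out_dir: str = "runs/latest"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: _coerce(k, v) for k, v in raw.items()})
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(sd.SimConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            cfg.sim = sd.SimConfig(**sim_raw)
        return cfg


def _coerce(key: str, value):
    if key == "bands":
        return tuple(tuple(float(x) for x in band) for band in value)
    if key in ("classifiers", "feature_sets"):
        return tuple(value)
    return value


def subject_session_averages(
    rec: Recording, config: PipelineConfig
) -> tuple[dict[int, pp.TrialSegment], dict]:
    """Condition one recording and average its surviving trials per session.

    Returns the session -> averaged-stimulation-segment map and a small
    bookkeeping dict (kept/rejected counts).
    """
    clean = pp.preprocess_recording(rec, bands=config.bands, notch_hz=config.notch_hz)
    segments = pp.segment_trials(
        clean,
        trial_s=config.sim.trial_s,
        n_trials_per_session=config.sim.n_trials_per_session,
    )
    kept, rejected = pp.reject_amplitude(segments, threshold=config.reject_uv)
    averages = pp.session_averages(kept)
    return averages, {"n_kept": len(kept), "n_rejected": len(rejected)}


def averages_by_target_frequency(
    averages: dict[int, pp.TrialSegment], plans: list[sd.SessionPlan]
) -> dict[float, pp.TrialSegment]:
    """Average the session averages of sessions sharing a target frequency.

    The grouping by *target* frequency is what makes the feature matrix
    diagnostic: within a group, normal-vision subjects attended the group
    frequency and CVD subjects its alternative.
    """
    by_freq: dict[float, list[pp.TrialSegment]] = {}
    for plan in plans:
        if plan.session_id in averages:
            by_freq.setdefault(plan.target_frequency, []).append(
                averages[plan.session_id]
            )
    return {f: pp.average_trials(segs) for f, segs in sorted(by_freq.items())}


def subject_feature_vector(
    rec: Recording,
    plans: list[sd.SessionPlan],
    config: PipelineConfig,
    subject_id: str = "",
    label: str = "unknown",
) -> ft.FeatureVector:
    """Recording -> canonical 16-element feature vector."""
    averages, _ = subject_session_averages(rec, config)
    by_freq = averages_by_target_frequency(averages, plans)
    return ft.extract_feature_vector(
        by_freq,
        channel_names=rec.channel_names,
        subject_id=subject_id,
        label=label,
        n_harmonics=config.n_harmonics,
        nperseg=config.nperseg,
        overlap=config.overlap,
    )


def cohort_feature_table(
    cohort: list[tuple[Recording, sd.SubjectProfile]],
    plans: list[sd.SessionPlan],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Feature matrix for a cohort: subject_id, label, 16 feature columns."""
    rows = []
    for rec, profile in cohort:
        fv = subject_feature_vector(
            rec, plans, config, subject_id=profile.subject_id, label=profile.condition
        )
        rows.append([fv.subject_id, fv.label] + fv.values.tolist())
    return pd.DataFrame(rows, columns=["subject_id", "label"] + ft.feature_names())


def diagnose_cohort(
    cohort: list[tuple[Recording, sd.SubjectProfile]],
    plans: list[sd.SessionPlan],
    config: PipelineConfig,
) -> list[dx.DiagnosisResult]:
    results = []
    for rec, profile in cohort:
        averages, _ = subject_session_averages(rec, config)
        results.append(
            dx.diagnose_from_averages(
                averages,
                plans,
                method=config.method,
                threshold=config.threshold,
                subject_id=profile.subject_id,
            )
        )
    return results


def classify_feature_table(
    table: pd.DataFrame, config: PipelineConfig
) -> dict[str, ml.ClassifierReport]:
    """Cross-validate every (classifier, feature set) pair on the table."""
    x = table[ft.feature_names()].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    reports = {}
    for clf in config.classifiers:
        for fset in config.feature_sets:
            reports[f"{clf}|{fset}"] = ml.kfold_cv(
                x,
                y,
                classifier=clf,
                feature_set=fset,
                k_folds=config.k_folds,
                seed=config.seed,
                smote_mode=config.smote_mode,
            )
    return reports


def _report_to_dict(rep: ml.ClassifierReport) -> dict:
    d = dataclasses.asdict(rep)
    d["confusion"] = dataclasses.asdict(rep.confusion)
    return d


def _diagnosis_to_dict(res: dx.DiagnosisResult) -> dict:
    return {
        "subject_id": res.subject_id,
        "call": res.call,
        "n_cvd_matches": res.n_cvd_matches,
        "severity_score": res.severity_score,
        "sessions": [dataclasses.asdict(r) for r in res.session_results],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write outputs and a run manifest under out_dir.

    On a stage failure the partial outputs are moved under ``failed/`` and a
    :class:`PipelineError` naming the stage is raised. A single-class cohort
    is not a failure: the classify stage records a refusal in the manifest
    and the run completes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_to_dict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        plans = sd.default_session_plans()
        cohort = sd.simulate_cohort(
            config.n_normal,
            config.n_cvd,
            cfg=config.sim,
            plans=plans,
            seed=config.seed,
            severity=config.severity,
            lapse_rate=config.lapse_rate,
        )
        (out / "plans.json").write_text(
            json.dumps([dataclasses.asdict(p) for p in plans], indent=2),
            encoding="utf-8",
        )
        truth = pd.DataFrame(
            [
                (p.subject_id, p.condition, p.severity, p.lapse_rate)
                for _, p in cohort
            ],
            columns=["subject_id", "condition", "severity", "lapse_rate"],
        )
        truth.to_csv(out / "truth.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_subjects": len(cohort),
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        manifest["outputs"]["plans"] = str(out / "plans.json")
        manifest["outputs"]["truth"] = str(out / "truth.csv")

        stage = "features"
        t0 = time.perf_counter()
        table = cohort_feature_table(cohort, plans, config)
        table.to_csv(out / "features.csv", index=False, float_format="%.12g")
        manifest["stages"]["features"] = {
            "n_rows": len(table),
            "n_feature_columns": len(ft.feature_names()),
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        manifest["outputs"]["features"] = str(out / "features.csv")

        stage = "diagnose"
        t0 = time.perf_counter()
        diagnoses = diagnose_cohort(cohort, plans, config)
        (out / "diagnosis.json").write_text(
            json.dumps([_diagnosis_to_dict(r) for r in diagnoses], indent=2),
            encoding="utf-8",
        )
        truth_map = {p.subject_id: p.condition for _, p in cohort}
        n_correct = sum(r.call == truth_map[r.subject_id] for r in diagnoses)
        manifest["stages"]["diagnose"] = {
            "n_subjects": len(diagnoses),
            "n_calls_matching_truth": n_correct,
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        manifest["outputs"]["diagnosis"] = str(out / "diagnosis.json")

        stage = "classify"
        t0 = time.perf_counter()
        labels = table["label"].unique()
        if len(labels) < 2:
            manifest["stages"]["classify"] = {
                "refused": "single_class_cohort",
                "classes_present": labels.tolist(),
            }
        else:
            reports = classify_feature_table(table, config)
            (out / "classification.json").write_text(
                json.dumps(
                    {k: _report_to_dict(v) for k, v in reports.items()}, indent=2
                ),
                encoding="utf-8",
            )
            manifest["stages"]["classify"] = {
                "n_reports": len(reports),
                "wall_s": round(time.perf_counter() - t0, 3),
            }
            manifest["outputs"]["classification"] = str(out / "classification.json")
    except PipelineError:
        raise
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        manifest["stages"][stage] = {"error": str(exc)}
        (failed / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str), encoding="utf-8"
        )
        raise PipelineError(stage, type(exc).__name__, str(exc)) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8"
    )
    return manifest


def _config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["channel_names"] = list(d["sim"]["channel_names"])
    return d
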