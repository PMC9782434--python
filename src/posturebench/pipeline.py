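"""End-to-end pipeline: simulate -> extract -> benchmark -> select.

Each stage is an importable function that also persists its output, so the
pipeline can be re-run from any stage's on-disk artifact: the feature table
is a CSV, benchmark outputs are per-combination confusion-matrix JSONs plus
per-sample score CSVs, and the selection report is written as CSV and JSON.
All randomness derives from the seeds recorded in :class:`RunConfig`, so a
given config reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bench as bench_mod
from .bench import (
    EXPERIMENTS,
    BenchResult,
    ClassifierSpec,
    ConfusionMatrix,
    CVScheme,
    Family,
    cross_validate,
    default_classifier_specs,
)
from .cohort import (
    CohortParams,
    EffectConfig,
    SubjectProfile,
    sample_cohort,
    simulate_session,
)
from .features import FEATURE_NAMES, assemble_features, feature_table
from .protocol import make_schedule
from .selection import SelectionReport, evaluate_bench

__all__ = [
    "RunConfig",
    "PipelineResult",
    "build_cohort",
    "build_feature_table",
    "run_bench",
    "load_bench_dir",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (all seeds explicit)."""

    n_pd: int = 20
    n_hc: int = 15
    effect_ml_amp_sd: float = 1.5
    effect_pelvis_gain_sd: float = 1.5
    on_normalization: float = 0.3
    accel_noise_ms2: float = 0.05
    orient_noise_deg: float = 0.2
    fs_hz: float = 100.0
    trial_duration_s: float = 34.0
    ramp_duration_s: float = 2.0
    n_repetitions: int = 3
    average_repetitions: bool = True
    cv_kind: str = "kfold"          # scheme for DT/KNN/SVM; ANN uses LOSO
    cv_k: int = 50
    threshold_pct: float = 80.0
    seed_cohort: int = 0
    seed_folds: int = 0
    seed_classifier: int = 0
    save_sessions: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def effect(self) -> EffectConfig:
        return EffectConfig(ml_amp_sd=self.effect_ml_amp_sd,
                            pelvis_gain_sd=self.effect_pelvis_gain_sd,
                            on_normalization=self.on_normalization)


@dataclass
class PipelineResult:
    config: RunConfig
    profiles: list[SubjectProfile]
    features: pd.DataFrame
    bench: list[BenchResult]
    report: SelectionReport


def _child_seed(*parts: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])


def build_cohort(config: RunConfig) -> list[SubjectProfile]:
    """Stage 1: draw the virtual cohort with the configured group contrasts."""
    params = CohortParams(accel_noise_ms2=config.accel_noise_ms2,
                          orient_noise_deg=config.orient_noise_deg)
    return sample_cohort(n_pd=config.n_pd, n_hc=config.n_hc,
                         effect=config.effect(),
                         rng_seed=np.random.default_rng(
                             _child_seed(config.seed_cohort, 0)),
                         params=params)


def _subject_state_vectors(profile: SubjectProfile, config: RunConfig,
                           index: int, out_dir: Path | None):
    """Simulate one subject-state's 18 trials and assemble feature rows."""
    sched = make_schedule(
        rng_seed=int(_child_seed(config.seed_cohort, 1, index)
                     .generate_state(1)[0] & 0x7FFFFFFF),
        n_repetitions=config.n_repetitions)
    noise_rng = np.random.default_rng(_child_seed(config.seed_cohort, 2,
                                                  index))
    sessions = []
    meta: dict = {"group": profile.group.value}
    for trial_idx, spec in sched:
        session = simulate_session(
            profile, spec, duration=config.trial_duration_s,
            fs=config.fs_hz, ramp_duration=config.ramp_duration_s,
            rng=noise_rng)
        sessions.append(session)
        if out_dir is not None:
            sdir = out_dir / "sessions" / \
                f"{profile.subject_id}_{profile.state.value}"
            sdir.mkdir(parents=True, exist_ok=True)
            for seg, stream in session.streams.items():
                stream.to_frame().to_csv(
                    sdir / f"trial{trial_idx:02d}_{seg.value}.csv",
                    index=False)
            meta[f"trial{trial_idx:02d}"] = {
                "level": spec.level.value,
                "start_side": spec.start_side.value,
                "fs": config.fs_hz,
                "duration": config.trial_duration_s,
            }
            (sdir / "manifest.json").write_text(json.dumps(meta, indent=2))

    if config.average_repetitions:
        return [assemble_features(sessions, group=profile.group.value)]
    by_type: dict[str, list] = {}
    for s in sessions:
        by_type.setdefault(s.spec.test_type, []).append(s)
    vectors = []
    for r in range(config.n_repetitions):
        subset = [reps[r] for reps in by_type.values()]
        vectors.append(assemble_features(subset, group=profile.group.value))
    return vectors


def build_feature_table(config: RunConfig,
                        profiles: list[SubjectProfile] | None = None,
                        out_dir: str | Path | None = None) -> pd.DataFrame:
    """Stage 2: simulate every subject-state's protocol and extract features."""
    if profiles is None:
        profiles = build_cohort(config)
    out_path = Path(out_dir) if out_dir is not None else None
    vectors = []
    for i, profile in enumerate(profiles):
        vectors.extend(_subject_state_vectors(
            profile, config, i,
            out_path if config.save_sessions else None))
    table = feature_table(vectors)
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path / "features.csv", index=False)
    return table


def run_bench(config: RunConfig, table: pd.DataFrame,
              out_dir: str | Path | None = None) -> list[BenchResult]:
    """Stage 3: cross-validate all 13 variants on all 4 experiments."""
    specs = default_classifier_specs(rng_seed=config.seed_classifier)
    results: list[BenchResult] = []
    for exp, spec in bench_mod.enumerate_bench(EXPERIMENTS, specs):
        scheme = (CVScheme(kind="loso", rng_seed=config.seed_folds)
                  if spec.family is Family.ANN
                  else CVScheme(kind=config.cv_kind, k=config.cv_k,
                                rng_seed=config.seed_folds))
        results.append(cross_validate(spec, exp, table, scheme))
    if out_dir is not None:
        out = Path(out_dir)
        (out / "scores").mkdir(parents=True, exist_ok=True)
        for res in results:
            stem = f"{res.experiment}__{res.classifier}"
            res.to_json(out / f"{stem}.json")
            res.scores.to_csv(out / "scores" / f"{stem}.csv", index=False)
    return results


def load_bench_dir(bench_dir: str | Path) -> list[BenchResult]:
    """Rebuild benchmark results from the on-disk JSON + score artifacts."""
    bench_dir = Path(bench_dir)
    results = []
    for path in sorted(bench_dir.glob("*.json")):
        payload = json.loads(path.read_text())
        cm = ConfusionMatrix(**payload["confusion"])
        scores_path = bench_dir / "scores" / f"{path.stem}.csv"
        scores = (pd.read_csv(scores_path) if scores_path.exists()
                  else pd.DataFrame(columns=["subject_id", "label", "score"]))
        sch = payload["scheme"]
        results.append(BenchResult(
            experiment=payload["experiment"],
            classifier=payload["classifier"],
            confusion=cm, scores=scores,
            scheme=CVScheme(kind=sch["kind"], k=sch["k"],
                            rng_seed=sch["rng_seed"]),
            n_folds=payload["n_folds"]))
    return results


def run_pipeline(config: RunConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage in order, optionally persisting all artifacts."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps({
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "feature_names": list(FEATURE_NAMES),
        }, indent=2))

    profiles = build_cohort(config)
    table = build_feature_table(config, profiles, out_dir=out)
    results = run_bench(config, table,
                        out_dir=None if out is None else out / "bench")
    report = evaluate_bench(results, threshold_pct=config.threshold_pct)
    if out is not None:
        report.to_frame().to_csv(out / "selection_report.csv", index=False)
        (out / "selection_best.json").write_text(
            json.dumps(report.best, indent=2))
    return PipelineResult(config=config, profiles=profiles, features=table,
                          bench=results, report=report)
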