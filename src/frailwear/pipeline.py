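"""End-to-end pipeline orchestration: simulate -> clean -> extract ->
select -> train -> evaluate, with a manifest for reproducibility.

Each stage writes its output under the run directory before the next stage
starts, so a failing stage aborts with its name while earlier outputs are
preserved. Rerunning with the same config and seed reproduces every numeric
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError, FrailwearError
from .evaluation import cross_validate, stratified_folds
from .features import build_matrix
from .modeling import ModelSpec, save_model, train, tune
from .segmentation import SegmentationConfig
from .selection import rfe
from .sessions import clean, write_sessions
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1


class PipelineStageError(FrailwearError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    unit: str = "phase"
    algorithm: str = "knn"
    selection_metric: str = "f1"
    folds: int = 5
    seed: int | None = None
    #: tune the grid once on the full feature set and freeze it through the
    #: elimination loop (set False to re-tune at every subset size)
    freeze_hyperparameters: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory for a pipeline run")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.get("cohort", {}))
        seg = SegmentationConfig(**raw.get("segmentation", {}))
        top = {k: v for k, v in raw.items() if k not in ("cohort", "segmentation")}
        return cls(cohort=cohort, segmentation=seg, **top)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage, returning the run directory.

    The directory ends up holding raw sessions, cleaned sessions, the
    feature matrix, the elimination trace, the tuned model, the evaluation
    report and a manifest tying them together.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "manifest_version": MANIFEST_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": _as_jsonable(config),
        "stages": {},
        "counts": {},
    }
    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        sessions = generate_cohort(cohort_cfg)
        write_sessions(sessions, out / "sessions")
        manifest["stages"]["simulate"] = "sessions"
        manifest["counts"]["sessions"] = len(sessions)
        logger.info("simulate: %d sessions", len(sessions))

        stage = "clean"
        cleaned, dropped = [], 0
        for s in sessions:
            c, n = clean(s, target_rate=config.segmentation.rate)
            cleaned.append(c)
            dropped += n
        write_sessions(cleaned, out / "cleaned")
        manifest["stages"]["clean"] = "cleaned"
        manifest["counts"]["hr_values_replaced"] = dropped
        logger.info("clean: %d anomalous HR values replaced", dropped)

        stage = "extract"
        matrix = build_matrix(cleaned, config.segmentation, unit=config.unit)
        matrix.to_csv(out / "features.csv")
        manifest["stages"]["extract"] = "features.csv"
        manifest["counts"]["records"] = len(matrix)
        manifest["counts"]["features"] = len(matrix.feature_names)
        logger.info("extract: %d records x %d features", len(matrix),
                    len(matrix.feature_names))

        stage = "select"
        folds = stratified_folds(matrix.y, k=config.folds, seed=config.seed)
        frozen = (tune(matrix, config.algorithm, k=config.folds,
                       seed=config.seed, folds=folds)
                  if config.freeze_hyperparameters else None)
        trace = rfe(matrix, config.algorithm, selection_metric=config.selection_metric,
                    k=config.folds, seed=config.seed, spec=frozen)
        trace.to_csv(out / "rfe_trace.csv")
        manifest["stages"]["select"] = "rfe_trace.csv"
        manifest["counts"]["selected_features"] = trace.best_size
        logger.info("select: best subset size %d", trace.best_size)

        stage = "train"
        best = matrix.select_features(list(trace.best_subset))
        spec = frozen or tune(best, config.algorithm, k=config.folds, seed=config.seed)
        model = train(best, spec, seed=config.seed)
        save_model(model, out / "model.joblib")
        manifest["stages"]["train"] = "model.joblib"
        manifest["model_spec"] = {"algorithm": spec.algorithm, "params": dict(spec.params)}

        stage = "evaluate"
        report = cross_validate(best, spec, k=config.folds, seed=config.seed)
        report.summary().to_csv(out / "evaluation.csv", index=False)
        report.confusion.to_csv(out / "confusion.csv")
        manifest["stages"]["evaluate"] = "evaluation.csv"
        manifest["metrics"] = {
            "accuracy": report.accuracy, "f1": report.f1,
            "sensitivity": report.sensitivity, "specificity": report.specificity,
        }
        logger.info("evaluate: accuracy %.4f f1 %.4f", report.accuracy, report.f1)
    except Exception as exc:  # annotate with the failing stage
        raise PipelineStageError(stage, exc) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
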