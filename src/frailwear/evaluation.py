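"""Stratified cross-validated evaluation and the phase-subset experiments.

Metrics follow the standard confusion-count definitions

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

computed per class one-vs-rest from the 3x3 confusion matrix. The report's
overall sensitivity/specificity/F1 are unweighted (macro) averages of the
per-class values; overall accuracy is the global trace / total. A
denominator of zero yields 0 and is flagged.

Folds are stratified at record level: within each class, records are
shuffled with the seed and dealt into k near-equal blocks, the remainder
distributed round-robin from a seeded starting fold, so per-fold class
proportions stay within one record of the global proportions. ``k = 1``
puts everything in one fold and ``k = n`` degenerates to leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ExperimentError, FrailwearError, StratificationError
from .segmentation import SegmentationConfig
from .sessions import PHASE_IDS, PHASE_NAMES
from .synthetic import SHOPPING_PHASES, STATIC_PHASES, WALKING_PHASES


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise FrailwearError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricValues:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    #: names of metrics whose denominator was zero (value reported as 0)
    zero_division: tuple[str, ...] = ()


def metrics(counts: ConfusionCounts) -> MetricValues:
    """Exact evaluation of the four confusion-count metrics."""
    if counts.total == 0:
        raise FrailwearError("metrics need at least one evaluated record")

    flagged: list[str] = []

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    sens = ratio("sensitivity", counts.tp, counts.tp + counts.fn)
    spec = ratio("specificity", counts.tn, counts.tn + counts.fp)
    f1 = ratio("f1", 2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    return MetricValues(acc, sens, spec, f1, tuple(flagged))


def stratified_folds(labels: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each record to one of k folds, preserving class proportions.

    Deterministic given (labels, k, seed). Raises when a class has fewer
    records than folds, except for the degenerate leave-one-out case
    ``k == len(labels)``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 1:
        raise StratificationError("k must be >= 1")
    if k == n:  # leave-one-out: stratification is vacuous
        return np.arange(n)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    rr = int(rng.integers(k))  # seeded round-robin start for remainders
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {cls!r} has {len(idx)} records but k={k} folds; "
                "stratification infeasible — reduce k or add records"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), k)
        counts = np.full(k, base)
        for j in range(rem):
            counts[(rr + j) % k] += 1
        rr = (rr + rem) % k
        pos = 0
        for f in range(k):
            folds[idx[pos : pos + counts[f]]] = f
            pos += counts[f]
    return folds


@dataclass
class EvalReport:
    """Cross-validation result: 3x3 confusion matrix plus overall and
    per-class metrics (overall sensitivity/specificity/F1 macro-averaged)."""

    confusion: pd.DataFrame  # rows = true class, columns = predicted
    per_class: dict[str, MetricValues]
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    folds: np.ndarray
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [{"class": "overall", "accuracy": self.accuracy, "f1": self.f1,
                 "sensitivity": self.sensitivity, "specificity": self.specificity}]
        for cls, m in self.per_class.items():
            rows.append({"class": cls, "accuracy": m.accuracy, "f1": m.f1,
                         "sensitivity": m.sensitivity, "specificity": m.specificity})
        return pd.DataFrame(rows)


def one_vs_rest_counts(confusion: pd.DataFrame, cls: str) -> ConfusionCounts:
    """Collapse a multiclass confusion matrix to counts for one positive class."""
    total = int(confusion.to_numpy().sum())
    tp = int(confusion.loc[cls, cls])
    fn = int(confusion.loc[cls].sum()) - tp
    fp = int(confusion[cls].sum()) - tp
    return ConfusionCounts(tp=tp, tn=total - tp - fn - fp, fp=fp, fn=fn)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            folds: np.ndarray, seed: int) -> EvalReport:
    classes = sorted(set(y_true))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    per_class = {cls: metrics(one_vs_rest_counts(conf, cls)) for cls in classes}
    return EvalReport(
        confusion=conf,
        per_class=per_class,
        accuracy=float(np.trace(conf.to_numpy()) / len(y_true)),
        f1=float(np.mean([m.f1 for m in per_class.values()])),
        sensitivity=float(np.mean([m.sensitivity for m in per_class.values()])),
        specificity=float(np.mean([m.specificity for m in per_class.values()])),
        folds=folds,
        seed=seed,
    )


def cross_validate(matrix, spec, k: int = 5, seed: int = 0,
                   folds: np.ndarray | None = None) -> EvalReport:
    """Stratified k-fold cross-validation of one model specification.

    Every record is predicted exactly once, by a model trained without it.
    """
    from .modeling import build_estimator  # late import avoids a cycle

    X, y = matrix.X, matrix.y
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    y_pred = np.empty(len(y), dtype=object)
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        est = build_estimator(spec, n_features=X.shape[1], seed=seed)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
    return report_from_predictions(y, y_pred.astype(str), folds, seed)


# ---------------------------------------------------------------------------
# Phase-subset experiments


@dataclass(frozen=True)
class PhaseExperiment:
    """A named restriction of the analysis to a subset of protocol phases,
    optionally merging some of them into one packed record per session."""

    name: str
    phase_ids: tuple[int, ...]
    pack_ids: tuple[int, ...] = ()
    packed_name: str = "packed_shopping"
    segmentation: SegmentationConfig | None = None

    def __post_init__(self) -> None:
        if not self.phase_ids:
            raise ExperimentError("phase_ids must be non-empty")
        bad = [p for p in (*self.phase_ids, *self.pack_ids) if p not in PHASE_NAMES]
        if bad:
            raise ExperimentError(f"unknown phase id(s) {bad}")
        if not set(self.pack_ids) <= set(self.phase_ids):
            raise ExperimentError("pack_ids must be a subset of phase_ids")


_WALK = tuple(sorted(WALKING_PHASES))
_SIT = tuple(sorted(STATIC_PHASES))
_SHOP = tuple(sorted(SHOPPING_PHASES))

#: The named experiment designs: full protocol, activity groupings, the
#: packed-shopping variants, and the informative single phases.
EXPERIMENTS: dict[str, PhaseExperiment] = {
    "all": PhaseExperiment("all", tuple(range(1, 15))),
    "walking": PhaseExperiment("walking", _WALK),
    "sitstand": PhaseExperiment("sitstand", _SIT),
    "shopping": PhaseExperiment("shopping", _SHOP),
    "packed": PhaseExperiment("packed", _SHOP, pack_ids=_SHOP),
    "walk_sit_packed": PhaseExperiment(
        "walk_sit_packed", tuple(range(1, 15)), pack_ids=_SHOP
    ),
}


def single_phase_experiment(phase_name: str) -> PhaseExperiment:
    if phase_name not in PHASE_IDS:
        raise ExperimentError(f"unknown phase name {phase_name!r}")
    return PhaseExperiment(f"phase:{phase_name}", (PHASE_IDS[phase_name],))


def run_experiment(sessions, experiment: PhaseExperiment, algorithm: str,
                   seed: int = 0, seg_config: SegmentationConfig | None = None,
                   spec=None, selection_metric: str = "f1", k: int = 5):
    """Run one phase-subset experiment end to end.

    Builds the phase-level matrix restricted to the experiment's phases
    (with packing applied), runs RF-ranked recursive feature elimination,
    and cross-validates the best-size subset. Returns (EvalReport, RfeTrace).
    Pass ``spec`` to freeze the classifier hyperparameters across subset
    sizes; otherwise the grid is re-tuned at every size.
    """
    from .features import build_matrix, pack_phases
    from .selection import rfe

    seg = seg_config or experiment.segmentation or SegmentationConfig()
    matrix = build_matrix(sessions, seg, unit="phase")
    sub = matrix.restrict_phases(experiment.phase_ids)
    if len(sub) == 0:
        raise ExperimentError(f"experiment {experiment.name!r}: empty phase restriction")
    if experiment.pack_ids:
        sub = pack_phases(sub, list(experiment.pack_ids), experiment.packed_name)

    trace = rfe(sub, algorithm, selection_metric=selection_metric, k=k,
                seed=seed, spec=spec)
    best = sub.select_features(list(trace.best_subset))
    folds = stratified_folds(best.y, k=k, seed=seed)
    if spec is None:
        from .modeling import tune
        spec = tune(best, algorithm, k=k, seed=seed, folds=folds)
    report = cross_validate(best, spec, k=k, seed=seed, folds=folds)
    return report, trace
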