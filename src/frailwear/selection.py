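"""Embedded feature selection: random-forest importance ranking driving
recursive feature elimination.

The ranking is the mean impurity-decrease importance of a 500-tree random
forest (seeded). Elimination starts from the full feature set; each
iteration cross-validates the classifier on the current subset, records the
metrics, removes the single lowest-ranked feature and re-ranks the
survivors, down to one feature. The same stratified folds are reused at
every subset size so the trace is comparable across sizes. The best size
maximises the selection metric (F1 by default); ties go to the smaller
subset (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import RankingError
from .evaluation import cross_validate, stratified_folds
from .features import FeatureMatrix
from .modeling import ModelSpec, tune

SELECTION_METRICS = ("f1", "accuracy", "sensitivity", "specificity")

#: Forest size used for importance ranking.
RANKING_N_TREES = 500


@dataclass(frozen=True)
class RankedFeatures:
    """Feature names in descending importance order with their scores."""

    names: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.scores):
            raise RankingError("names and scores must have equal length")


def rank_features(matrix: FeatureMatrix, seed: int = 0,
                  n_trees: int = RANKING_N_TREES) -> RankedFeatures:
    """Rank all features by random-forest impurity-decrease importance.

    Deterministic given the seed; ties keep the matrix's column order.
    """
    if len(matrix.feature_names) < 1:
        raise RankingError("matrix has no features to rank")
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise RankingError("feature ranking needs at least two classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(matrix.X, y)
    scores = forest.feature_importances_
    order = np.argsort(-scores, kind="stable")
    return RankedFeatures(
        names=tuple(matrix.feature_names[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
    )


@dataclass(frozen=True)
class RfeStep:
    """One elimination iteration: the evaluated subset, its ranking, its
    cross-validated metrics, and the feature removed afterwards."""

    size: int
    features: tuple[str, ...]
    ranking: RankedFeatures
    metrics: dict[str, float]
    removed: str | None


@dataclass
class RfeTrace:
    steps: list[RfeStep]
    best_size: int
    best_subset: tuple[str, ...]
    selection_metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"size": s.size, **s.metrics, "removed": s.removed or "",
                 "features": ";".join(s.features)}
                for s in self.steps
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def rfe(matrix: FeatureMatrix, algorithm: str, selection_metric: str = "f1",
        k: int = 5, seed: int = 0, spec: ModelSpec | None = None,
        n_trees: int = RANKING_N_TREES) -> RfeTrace:
    """Recursive feature elimination with random-forest re-ranking.

    Produces exactly ``n_features`` steps (sizes n..1). At each size the
    classifier is evaluated by stratified k-fold cross-validation — with its
    hyperparameter grid re-tuned on the subset unless ``spec`` freezes one
    setting — then the lowest-ranked surviving feature is removed and the
    survivors re-ranked.
    """
    if len(matrix.feature_names) == 0:
        raise RankingError("cannot run elimination with zero features")
    if selection_metric not in SELECTION_METRICS:
        raise RankingError(
            f"unknown selection metric {selection_metric!r}; "
            f"expected one of {SELECTION_METRICS}"
        )
    folds = stratified_folds(matrix.y, k=k, seed=seed)

    survivors = list(matrix.feature_names)
    steps: list[RfeStep] = []
    while survivors:
        sub = matrix.select_features(survivors)
        ranking = rank_features(sub, seed=seed, n_trees=n_trees)
        step_spec = spec if spec is not None else tune(sub, algorithm, k=k,
                                                       seed=seed, folds=folds)
        report = cross_validate(sub, step_spec, k=k, seed=seed, folds=folds)
        removed = ranking.names[-1] if len(survivors) > 1 else None
        steps.append(
            RfeStep(
                size=len(survivors),
                features=tuple(survivors),
                ranking=ranking,
                metrics={
                    "accuracy": report.accuracy,
                    "f1": report.f1,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                },
                removed=removed,
            )
        )
        if removed is None:
            break
        survivors.remove(removed)

    best = min(steps, key=lambda s: (-s.metrics[selection_metric], s.size))
    return RfeTrace(steps=steps, best_size=best.size, best_subset=best.features,
                    selection_metric=selection_metric)
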