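"""The four classifier families and their hyperparameter grids.

The analysis compares k-nearest neighbours, support vector machines, random
forests and naive Bayes over fixed grids:

* k-NN: odd k from 1 up to floor(sqrt(n_rows));
* SVM: cost {0.1, 1, 10, 100} x gamma {0.5, 1, 2} x kernel
  {radial, polynomial, linear, sigmoid} (gamma is ignored by the linear
  kernel); multiclass via one-vs-one voting;
* RF: trees {10, 100, 200, 500, 1000} x variables-per-split {10, 25, 50}
  (clamped to the feature count of the training matrix);
* NB: use_kernel {True, False} x use_poisson {True, False}. The Poisson
  likelihood is honoured only for non-negative integer-valued features
  (heart rate); elsewhere it falls back to the Gaussian/kernel density with
  a logged warning.

Distance- and kernel-based methods (k-NN, SVM) see z-standardised features,
with the scaler fitted on the training folds only; RF and NB consume raw
features.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, ContractError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

ALGORITHMS = ("knn", "svm", "rf", "nb")

SVM_COSTS = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMAS = (0.5, 1.0, 2.0)
SVM_KERNELS = ("radial", "polynomial", "linear", "sigmoid")
RF_N_TREES = (10, 100, 200, 500, 1000)
RF_N_VARS = (10, 25, 50)

_SKLEARN_KERNEL = {"radial": "rbf", "polynomial": "poly", "linear": "linear",
                   "sigmoid": "sigmoid"}

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """One algorithm plus one point of its hyperparameter grid."""

    algorithm: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.algorithm == "knn":
            k = self.params.get("k", 1)
            if k < 1 or k % 2 == 0:
                raise ConfigurationError(f"knn k must be odd and positive, got {k}")
        object.__setattr__(self, "params", dict(self.params))


def grid_for(algorithm: str, n_rows: int) -> list[ModelSpec]:
    """The full hyperparameter grid of one algorithm, in documented order.

    The k-NN grid runs over odd k up to floor(sqrt(n_rows)); the other grids
    are the Cartesian products of their printed value sets.
    """
    if n_rows < 1:
        raise ConfigurationError("n_rows must be >= 1")
    if algorithm == "knn":
        k_max = int(np.floor(np.sqrt(n_rows)))
        return [ModelSpec("knn", {"k": k}) for k in range(1, max(k_max, 1) + 1, 2)]
    if algorithm == "svm":
        return [
            ModelSpec("svm", {"cost": c, "gamma": g, "kernel": kern})
            for c, g, kern in itertools.product(SVM_COSTS, SVM_GAMMAS, SVM_KERNELS)
        ]
    if algorithm == "rf":
        return [
            ModelSpec("rf", {"n_trees": n, "n_vars_sampled": m})
            for n, m in itertools.product(RF_N_TREES, RF_N_VARS)
        ]
    if algorithm == "nb":
        return [
            ModelSpec("nb", {"use_kernel": uk, "use_poisson": up})
            for uk, up in itertools.product((True, False), (True, False))
        ]
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


class NaiveBayes(BaseEstimator, ClassifierMixin):
    """Per-feature class-conditional naive Bayes.

    Likelihood per feature: Poisson (when ``use_poisson`` and the feature is
    non-negative integer-valued on the training data), otherwise a Gaussian
    kernel density estimate when ``use_kernel``, otherwise a Gaussian.
    """

    def __init__(self, use_kernel: bool = False, use_poisson: bool = False):
        self.use_kernel = use_kernel
        self.use_poisson = use_poisson

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.log_priors_ = np.log(counts / len(y))
        n_features = X.shape[1]
        self._poisson_ok = np.array([
            self.use_poisson
            and np.all(X[:, j] >= 0)
            and np.allclose(X[:, j], np.rint(X[:, j]))
            for j in range(n_features)
        ])
        if self.use_poisson and not self._poisson_ok.all():
            logger.warning(
                "use_poisson ignored for %d/%d non-integer or negative feature(s)",
                int((~self._poisson_ok).sum()), n_features,
            )
        var_floor = 1e-9 * max(float(X.var(axis=0).max()), 1.0)
        self._models: list[list[tuple]] = []
        for c in self.classes_:
            Xc = X[y == c]
            feats = []
            for j in range(n_features):
                col = Xc[:, j]
                if self._poisson_ok[j]:
                    feats.append(("poisson", max(col.mean(), 1e-9)))
                elif self.use_kernel and len(col) > 1 and col.std() > 0:
                    feats.append(("kde", stats.gaussian_kde(col)))
                else:
                    feats.append(("gauss", (col.mean(), np.sqrt(col.var() + var_floor))))
            self._models.append(feats)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.tile(self.log_priors_, (len(X), 1))
        for ci in range(len(self.classes_)):
            for j, (kind, param) in enumerate(self._models[ci]):
                col = X[:, j]
                if kind == "poisson":
                    ll = stats.poisson.logpmf(np.rint(np.maximum(col, 0)), param)
                elif kind == "kde":
                    ll = np.log(np.maximum(param.evaluate(col), 1e-300))
                else:
                    mu, sd = param
                    ll = stats.norm.logpdf(col, mu, sd)
                jll[:, ci] += ll
        return jll

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def build_estimator(spec: ModelSpec, n_features: int, seed: int = 0) -> BaseEstimator:
    """Instantiate the sklearn estimator (plus scaler where appropriate)."""
    p = spec.params
    if spec.algorithm == "knn":
        est = KNeighborsClassifier(n_neighbors=p.get("k", 1))
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if spec.algorithm == "svm":
        kernel = p.get("kernel", "radial")
        if kernel not in _SKLEARN_KERNEL:
            raise ConfigurationError(f"unknown SVM kernel {kernel!r}")
        if kernel == "linear" and "gamma" in p:
            logger.debug("gamma ignored for linear kernel")
        est = SVC(
            C=p.get("cost", 1.0),
            gamma=p.get("gamma", "scale"),
            kernel=_SKLEARN_KERNEL[kernel],
            decision_function_shape="ovo",
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if spec.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", 500),
            max_features=min(p.get("n_vars_sampled", 10), n_features),
            random_state=seed,
        )
    if spec.algorithm == "nb":
        return NaiveBayes(use_kernel=p.get("use_kernel", False),
                          use_poisson=p.get("use_poisson", False))
    raise ConfigurationError(f"unknown algorithm {spec.algorithm!r}")


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature names it was trained on."""

    spec: ModelSpec
    estimator: BaseEstimator
    feature_names: list[str]
    classes: list[str]


def train(matrix: FeatureMatrix, spec: ModelSpec, seed: int = 0) -> TrainedModel:
    if len(matrix) == 0:
        raise ConfigurationError("cannot train on an empty matrix")
    est = build_estimator(spec, n_features=len(matrix.feature_names), seed=seed)
    est.fit(matrix.X, matrix.y)
    return TrainedModel(spec=spec, estimator=est,
                        feature_names=list(matrix.feature_names),
                        classes=sorted(set(matrix.y)))


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    if list(matrix.feature_names) != list(model.feature_names):
        raise ContractError(
            "prediction matrix feature names differ from the training features"
        )
    return model.estimator.predict(matrix.X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "spec": {"algorithm": model.spec.algorithm, "params": dict(model.spec.params)},
            "estimator": model.estimator,
            "feature_names": model.feature_names,
            "classes": model.classes,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ContractError(f"unsupported model file version {blob.get('format_version')}")
    return TrainedModel(
        spec=ModelSpec(blob["spec"]["algorithm"], blob["spec"]["params"]),
        estimator=blob["estimator"],
        feature_names=blob["feature_names"],
        classes=blob["classes"],
    )


def tune(matrix: FeatureMatrix, algorithm: str, k: int = 5, seed: int = 0,
         folds: np.ndarray | None = None) -> ModelSpec:
    """Grid search by mean cross-validated macro F1.

    Evaluates every grid member with the same stratified k-fold split and
    returns the best; ties go to the earlier grid member (documented grid
    order), which for k-NN means the smaller k.
    """
    from .evaluation import stratified_folds  # late import avoids a cycle

    X, y = matrix.X, matrix.y
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    grid = grid_for(algorithm, n_rows=len(matrix))
    best_spec, best_score = None, -np.inf
    for spec in grid:
        scores = []
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            est = build_estimator(spec, n_features=X.shape[1], seed=seed)
            est.fit(X[tr], y[tr])
            scores.append(f1_score(y[te], est.predict(X[te]),
                                   average="macro", zero_division=0))
        score = float(np.mean(scores))
        if score > best_score:
            best_spec, best_score = spec, score
    return best_spec
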