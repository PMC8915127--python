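"""Binary cry / non-cry classification.

Eight classifier variants are tuned by grid search under 3-fold stratified
cross-validation on a 60/40 stratified train/test split: K-nearest
neighbours, linear discriminant analysis, logistic regression (tuned through
its decision cut-off on the cry probability), random forest, a multi-layer
perceptron, and support vector machines with linear, polynomial and Gaussian
kernels.  Two tuning strategies are supported: selecting the grid point with
the best mean CV accuracy, or with the best mean CV precision (fewest false
cries — the safer choice when extracted cries feed downstream vocal-
development statistics).  The scaler+PCA projection is fitted on the
training split only and stored inside the classifier artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .audio_io import AudioInputError
from .features import FeatureMatrix, prune_null_columns
from .reduction import ProjectionModel, fit_projection, project

POSITIVE_LABEL = "cry"
NEGATIVE_LABEL = "non_cry"

METHODS = ("knn", "lda", "lr", "rf", "mlp", "svm_linear", "svm_poly", "svm_rbf")


class ThresholdedLogisticRegression(BaseEstimator, ClassifierMixin):
    """Logistic regression whose positive decision uses a tunable cut-off.

    ``cutoff`` thresholds the predicted cry probability: cut-off 0 labels
    every segment cry, cut-off 1 labels none.
    """

    def __init__(self, cutoff: float = 0.5, max_iter: int = 1000):
        self.cutoff = cutoff
        self.max_iter = max_iter

    def fit(self, X, y):
        self.base_ = LogisticRegression(max_iter=self.max_iter)
        self.base_.fit(X, y)
        self.classes_ = self.base_.classes_
        return self

    def predict_proba(self, X):
        return self.base_.predict_proba(X)

    def predict(self, X):
        pos = list(self.classes_).index(POSITIVE_LABEL)
        proba = self.base_.predict_proba(X)[:, pos]
        neg = self.classes_[1 - pos]
        return np.where(proba >= self.cutoff, POSITIVE_LABEL, neg)


def make_estimator(method: str, seed: int = 0) -> BaseEstimator:
    """A fresh untuned estimator for one of the supported methods."""
    if method == "knn":
        return KNeighborsClassifier()
    if method == "lda":
        return LinearDiscriminantAnalysis()
    if method == "lr":
        return ThresholdedLogisticRegression()
    if method == "rf":
        return RandomForestClassifier(random_state=seed)
    if method == "mlp":
        return MLPClassifier(random_state=seed, max_iter=400)
    if method in ("svm_linear", "svm_poly", "svm_rbf"):
        kernel = {"svm_linear": "linear", "svm_poly": "poly", "svm_rbf": "rbf"}[method]
        return SVC(kernel=kernel, random_state=seed)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def param_grid(method: str) -> list[dict[str, Any]]:
    """The default hyper-parameter grid per method."""
    if method == "knn":
        grid = {"n_neighbors": [1, 3, 5, 11, 15], "metric": ["manhattan", "euclidean"]}
    elif method == "lda":
        grid = {"solver": ["svd", "lsqr", "eigen"]}
    elif method == "lr":
        grid = {"cutoff": [0.1, 0.2, 0.5, 0.7]}
    elif method == "rf":
        grid = {"n_estimators": [5, 10, 20, 50, 100, 300], "criterion": ["gini", "entropy"]}
    elif method == "mlp":
        grid = {
            "hidden_layer_sizes": [
                (n,) * layers for layers in (1, 2, 5) for n in (1, 2, 5, 10, 20, 30)
            ],
            "activation": ["identity", "logistic", "tanh", "relu"],
        }
    elif method == "svm_linear":
        grid = {}
    elif method == "svm_poly":
        grid = {"degree": [1, 2, 3, 4]}
    elif method == "svm_rbf":
        grid = {
            "C": [0.01, 0.1, 1, 10, 100, 1e3, 1e4],
            "gamma": [0.0001, 0.001, 0.01, 0.1, 1, 5, 10, 100],
        }
    else:
        raise ValueError(f"unknown method {method!r}")
    return list(ParameterGrid(grid))


@dataclass
class TrainingProtocol:
    test_fraction: float = 0.4
    cv_folds: int = 3
    strategy: str = "precision"  # "accuracy" or "precision"
    seed: int = 0
    grids: dict[str, list[dict[str, Any]]] | None = None

    def grid_for(self, method: str) -> list[dict[str, Any]]:
        if self.grids and method in self.grids:
            return self.grids[method]
        return param_grid(method)


@dataclass
class EvalReport:
    """Confusion counts and the derived metrics, as percentages."""

    tp: int
    fp: int
    fn: int
    tn: int
    degenerate_precision: bool = False

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 0.0
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 0.0
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.fn + self.tn
        return 100.0 * (self.tp + self.tn) / n if n else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


@dataclass
class CryClassifier:
    """A trained cry detector: feature schema + projection + tuned estimator."""

    method: str
    chosen_params: dict[str, Any]
    projection: ProjectionModel
    estimator: BaseEstimator
    schema: list[str]
    protocol: TrainingProtocol
    cv_results: list[dict[str, Any]] = field(default_factory=list)

    def predict_matrix(self, matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Labels and scores for a batch of feature rows."""
        scores = np.full(matrix.n_rows, np.nan)
        X = project(self.projection, matrix.select_columns(self.schema))
        labels = self.estimator.predict(X)
        if hasattr(self.estimator, "predict_proba"):
            classes = list(self.estimator.classes_)
            scores = self.estimator.predict_proba(X)[:, classes.index(POSITIVE_LABEL)]
        elif hasattr(self.estimator, "decision_function"):
            scores = np.asarray(self.estimator.decision_function(X), dtype=float)
        return np.asarray(labels), scores

    def predict(self, features: np.ndarray, columns: list[str]) -> tuple[str, float]:
        """Label and score for a single feature vector."""
        m = FeatureMatrix(np.atleast_2d(features), list(columns))
        labels, scores = self.predict_matrix(m)
        return str(labels[0]), float(scores[0])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "CryClassifier":
        return joblib.load(path)


def binarise_labels(labels: list[str]) -> list[str]:
    """Collapse the six annotation classes to cry / non_cry."""
    return [POSITIVE_LABEL if l == "cry" else NEGATIVE_LABEL for l in labels]


def split_train_test(
    matrix: FeatureMatrix, protocol: TrainingProtocol
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded stratified 60/40 split of a labelled feature matrix."""
    if matrix.labels is None:
        raise AudioInputError("split requires labels")
    y = binarise_labels(matrix.labels)
    if len(set(y)) < 2:
        raise AudioInputError("both classes must be present to split")
    idx = np.arange(matrix.n_rows)
    tr, te = train_test_split(
        idx,
        test_size=protocol.test_fraction,
        stratify=y,
        random_state=protocol.seed,
    )
    def take(rows):
        return FeatureMatrix(
            matrix.values[rows], list(matrix.columns), [y[i] for i in rows]
        )
    return take(tr), take(te)


def _counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    t = np.asarray(y_true) == POSITIVE_LABEL
    p = np.asarray(y_pred) == POSITIVE_LABEL
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return tp, fp, fn, tn


def _cv_score(est, X, y, folds, strategy, seed) -> float:
    """Mean CV score; -inf when a candidate cannot be fitted (e.g. a KNN
    neighbour count exceeding the fold size on small corpora)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, va in skf.split(X, y):
        model = clone(est)
        try:
            model.fit(X[tr], y[tr])
            pred = model.predict(X[va])
        except (ValueError, np.linalg.LinAlgError):
            return float("-inf")
        tp, fp, fn, tn = _counts(y[va], pred)
        if strategy == "precision":
            scores.append(tp / (tp + fp) if tp + fp else 0.0)
        else:
            scores.append((tp + tn) / len(va))
    return float(np.mean(scores))


def tune_and_fit(
    train: FeatureMatrix, method: str, protocol: TrainingProtocol
) -> CryClassifier:
    """Grid-search a method under 3-fold CV and refit on all training rows.

    The null-column pruning and the scaler+PCA projection are fitted on the
    training rows only; CV runs on the projected features.  The selection
    metric is mean CV accuracy or mean CV precision per the protocol.
    """
    if train.labels is None:
        raise AudioInputError("training requires labels")
    if protocol.strategy not in ("accuracy", "precision"):
        raise ValueError("strategy must be 'accuracy' or 'precision'")
    pruned, schema = prune_null_columns(
        FeatureMatrix(train.values, list(train.columns), train.labels)
    )
    projection = fit_projection(pruned)
    X = project(projection, pruned)
    y = np.asarray(binarise_labels(train.labels))
    if len(set(y)) < 2:
        raise AudioInputError("both classes must be present to train")
    cv_results = []
    best_score, best_params = -np.inf, {}
    for params in protocol.grid_for(method):
        est = make_estimator(method, protocol.seed).set_params(**params)
        score = _cv_score(est, X, y, protocol.cv_folds, protocol.strategy, protocol.seed)
        cv_results.append({"params": params, "cv_score": score})
        if score > best_score:
            best_score, best_params = score, params
    final = make_estimator(method, protocol.seed).set_params(**best_params)
    final.fit(X, y)
    return CryClassifier(
        method=method,
        chosen_params=best_params,
        projection=projection,
        estimator=final,
        schema=schema,
        protocol=protocol,
        cv_results=cv_results,
    )


def cv_score_of_params(
    train: FeatureMatrix,
    method: str,
    params: dict[str, Any],
    protocol: TrainingProtocol,
    metric: str,
) -> float:
    """Mean CV score of one parameter set under a chosen metric."""
    pruned, _ = prune_null_columns(train)
    projection = fit_projection(pruned)
    X = project(projection, pruned)
    y = np.asarray(binarise_labels(train.labels))
    est = make_estimator(method, protocol.seed).set_params(**params)
    return _cv_score(est, X, y, protocol.cv_folds, metric, protocol.seed)


def evaluate(model: CryClassifier, test: FeatureMatrix) -> EvalReport:
    """Confusion-matrix metrics on a labelled test set (cry = positive)."""
    if test.labels is None or test.n_rows == 0:
        raise AudioInputError("evaluation requires a non-empty labelled set")
    y_true = np.asarray(binarise_labels(test.labels))
    y_pred, _ = model.predict_matrix(test)
    tp, fp, fn, tn = _counts(y_true, y_pred)
    return EvalReport(tp, fp, fn, tn, degenerate_precision=(tp + fp == 0))
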