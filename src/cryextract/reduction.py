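"""Standard scaling and PCA dimensionality reduction.

Features are standardised per column, X' = (X - m) / s, with the population
(divide-by-n) standard deviation, then projected onto the smallest number of
principal components whose cumulative explained-variance ratio reaches 95%.
The fitted scaler + loadings travel with the classifier as one artifact so
the train-time transform is reproduced exactly at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .audio_io import AudioInputError
from .features import FeatureMatrix

VARIANCE_TARGET = 0.95


@dataclass
class ProjectionModel:
    """A frozen standardise-then-project transform."""

    columns: list[str]
    feature_means: np.ndarray
    feature_stds: np.ndarray
    components: np.ndarray  # (n_components, n_features) loadings
    explained_variance_ratios: np.ndarray
    explained_variances: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def n_components_for_ratios(ratios: np.ndarray, target: float = VARIANCE_TARGET) -> int:
    """Smallest k with cumulative explained-variance ratio >= target."""
    cum = np.cumsum(np.asarray(ratios, dtype=np.float64))
    idx = np.searchsorted(cum, target - 1e-12)
    return int(min(idx + 1, len(cum)))


def fit_projection(
    train: FeatureMatrix, variance_target: float = VARIANCE_TARGET
) -> ProjectionModel:
    """Fit the scaler and PCA on training rows, keeping 95% of the variance.

    Residual constant columns (which cannot be standardised) are dropped
    with a warning.  Component signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    if train.n_rows < 2:
        raise AudioInputError("need at least 2 rows to fit a projection")
    X = train.values
    stds = X.std(axis=0)  # population (ddof=0) std, matching the scaling rule
    constant = stds == 0.0
    if constant.any():
        dropped = [c for c, bad in zip(train.columns, constant) if bad]
        warnings.warn(f"dropping constant feature columns: {dropped}")
        keep = [c for c in train.columns if c not in dropped]
        train = train.select_columns(keep)
        X = train.values
        stds = X.std(axis=0)
    means = X.mean(axis=0)
    Z = (X - means) / stds
    pca = PCA(n_components=min(Z.shape))
    pca.fit(Z)
    k = n_components_for_ratios(pca.explained_variance_ratio_, variance_target)
    components = pca.components_[:k].copy()
    # deterministic sign: largest |loading| positive per component
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return ProjectionModel(
        columns=list(train.columns),
        feature_means=means,
        feature_stds=stds,
        components=components,
        explained_variance_ratios=pca.explained_variance_ratio_[:k].copy(),
        explained_variances=pca.explained_variance_[:k].copy(),
    )


def project(model: ProjectionModel, matrix: FeatureMatrix) -> np.ndarray:
    """Apply the frozen transform: ((X - m) / s) @ components.T."""
    aligned = matrix.select_columns(model.columns)
    Z = (aligned.values - model.feature_means) / model.feature_stds
    return Z @ model.components.T
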