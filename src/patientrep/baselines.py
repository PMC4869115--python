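"""Shallow feature-learning baselines.

Each baseline applies one transformation to the scaled raw matrix and is
exposed behind the same fit/transform contract as the deep learner:

* ``rawfeat`` — identity pass-through of the filtered, scaled matrix;
* ``pca``    — principal component scores (default 100 components);
* ``ica``    — independent component scores (default 100 components);
* ``kmeans`` — Euclidean distance to each cluster centroid (default 500);
* ``gmm``    — posterior responsibilities under a full-covariance Gaussian
  mixture (default 200 components), or per-component log-likelihoods.

The decompositions, clustering and mixtures delegate to scikit-learn; the
classes here fix the feature mappings (centroid distances, responsibilities)
and the serialization contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array, check_is_fitted

_DEFAULT_COMPONENTS = {"pca": 100, "ica": 100, "kmeans": 500, "gmm": 200}


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


class RawFeatures(TransformerMixin, BaseEstimator):
    """The unlearned baseline: the filtered, scaled matrix itself."""

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse="csr")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, accept_sparse="csr")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} columns, got {X.shape[1]}")
        return X


class _DenseWrapper(TransformerMixin, BaseEstimator):
    """Shared plumbing: densify, validate dimensions, delegate to sklearn."""

    def _build(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _check_fit_input(self, X: np.ndarray) -> None:
        pass

    def fit(self, X, y=None):
        X = _dense(check_array(X, accept_sparse="csr"))
        self._check_fit_input(X)
        self.estimator_ = self._build().fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_transform_input(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = _dense(check_array(X, accept_sparse="csr"))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} columns, got {X.shape[1]}")
        return X

    def transform(self, X):
        return self.estimator_.transform(self._check_transform_input(X))


class PCAScores(_DenseWrapper):
    """Principal component scores of the scaled matrix."""

    def __init__(self, n_components: int = 100, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def _check_fit_input(self, X):
        if X.shape[0] and np.ptp(X) == 0:
            raise ValueError("constant matrix: principal components are undefined")

    def _build(self):
        return PCA(n_components=self.n_components, random_state=self.random_state)


class ICAScores(_DenseWrapper):
    """Independent component scores (FastICA with PCA whitening)."""

    def __init__(
        self,
        n_components: int = 100,
        random_state: int = 0,
        max_iter: int = 500,
        tol: float = 1e-3,
    ):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def _check_fit_input(self, X):
        if X.shape[0] and np.ptp(X) == 0:
            raise ValueError("constant matrix: independent components are undefined")

    def _build(self):
        return FastICA(
            n_components=self.n_components,
            random_state=self.random_state,
            whiten="unit-variance",
            max_iter=self.max_iter,
            tol=self.tol,
        )


class KMeansDistanceFeatures(_DenseWrapper):
    """Distance-to-centroid features from k-means clustering.

    Feature j of a patient is the Euclidean distance to centroid j, so the
    output is non-negative with shape (n_patients, n_clusters) and the
    argmin over features is the cluster assignment.
    """

    def __init__(self, n_components: int = 500, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def _build(self):
        return KMeans(
            n_clusters=self.n_components, random_state=self.random_state, n_init=1
        )


class GMMPosteriorFeatures(_DenseWrapper):
    """Gaussian-mixture features: posterior responsibilities or log-likelihoods.

    ``feature_mode="responsibility"`` (default) returns the posterior
    probability of each mixture component given the patient (rows sum to 1);
    ``"loglik"`` returns per-component Gaussian log-densities.  Full
    covariances on sparse [0,1] data are near-singular, hence the diagonal
    regularization ``reg_covar``.
    """

    def __init__(
        self,
        n_components: int = 200,
        covariance_type: str = "full",
        reg_covar: float = 1e-6,
        random_state: int = 0,
        feature_mode: str = "responsibility",
        max_iter: int = 100,
    ):
        self.n_components = n_components
        self.covariance_type = covariance_type
        self.reg_covar = reg_covar
        self.random_state = random_state
        self.feature_mode = feature_mode
        self.max_iter = max_iter

    def _build(self):
        if self.feature_mode not in ("responsibility", "loglik"):
            raise ValueError("feature_mode must be 'responsibility' or 'loglik'")
        return GaussianMixture(
            n_components=self.n_components,
            covariance_type=self.covariance_type,
            reg_covar=self.reg_covar,
            random_state=self.random_state,
            max_iter=self.max_iter,
        )

    def transform(self, X):
        X = self._check_transform_input(X)
        if self.feature_mode == "responsibility":
            return self.estimator_.predict_proba(X)
        return self._component_log_likelihood(X)

    def _component_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        gmm = self.estimator_
        if gmm.covariance_type != "full":
            raise ValueError("loglik features require full covariances")
        n, d = X.shape
        out = np.empty((n, gmm.n_components))
        for k in range(gmm.n_components):
            chol = gmm.precisions_cholesky_[k]  # Sigma^-1 = chol @ chol.T
            y = (X - gmm.means_[k]) @ chol
            log_det = np.sum(np.log(np.diag(chol)))
            out[:, k] = -0.5 * (d * np.log(2 * np.pi) + np.sum(y**2, axis=1)) + log_det
        return out


@dataclass
class BaselineSpec:
    """Declarative description of one shallow baseline.

    ``n_components=None`` selects the conventional defaults: 100 for PCA and
    ICA, 500 clusters for k-means, 200 mixtures for the GMM.
    """

    method: str
    n_components: int | None = None
    seed: int = 0
    extras: dict[str, Any] = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("rawfeat", "pca", "ica", "kmeans", "gmm"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.n_components is None and self.method != "rawfeat":
            self.n_components = _DEFAULT_COMPONENTS[self.method]
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def make_baseline(spec: BaselineSpec) -> BaseEstimator:
    """Instantiate the transformer described by a :class:`BaselineSpec`."""
    if spec.method == "rawfeat":
        return RawFeatures()
    if spec.method == "pca":
        return PCAScores(spec.n_components, random_state=spec.seed, **spec.extras)
    if spec.method == "ica":
        return ICAScores(spec.n_components, random_state=spec.seed, **spec.extras)
    if spec.method == "kmeans":
        return KMeansDistanceFeatures(
            spec.n_components, random_state=spec.seed, **spec.extras
        )
    return GMMPosteriorFeatures(spec.n_components, random_state=spec.seed, **spec.extras)


def fit_baseline(spec: BaselineSpec, X) -> BaseEstimator:
    """Fit the baseline described by ``spec`` on a scaled matrix."""
    model = make_baseline(spec)
    if spec.method in ("pca", "ica") and spec.n_components > X.shape[1]:
        raise ValueError(
            f"{spec.method} needs n_components <= {X.shape[1]} input columns"
        )
    return model.fit(X)


def transform_baseline(model: BaseEstimator, X) -> np.ndarray:
    return model.transform(X)


def save_baseline(model: BaseEstimator, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "model.json").write_text(
        json.dumps({"kind": "baseline", "class": type(model).__name__})
    )
    joblib.dump(model, directory / "model.joblib")


def load_baseline(directory) -> BaseEstimator:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("kind") != "baseline":
        raise ValueError(f"{directory} does not contain a baseline model")
    return joblib.load(directory / "model.joblib")
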