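"""One-vs-all future-disease classification.

An independent random forest is fit per disease on any patient
representation; its positive-class probability gives each patient's score
for developing that disease.  Scores for diseases a patient already has
(re-diagnoses) are masked and excluded from every downstream metric and
ranking.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_array, check_is_fitted

from .labels import DiseaseLabelMatrix


@dataclass
class PredictionMatrix:
    """Per-patient disease-probability vectors with a prior-diagnosis mask."""

    scores: np.ndarray  # float (n_patients, n_diseases)
    mask: np.ndarray  # bool; True = masked (prior diagnosis), undefined cell
    patient_ids: np.ndarray
    disease_ids: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.disease_ids = np.asarray(self.disease_ids, dtype=object)
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask must share a shape")
        if self.scores.shape != (len(self.patient_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match the id axes")
        unmasked = self.scores[~self.mask]
        if unmasked.size and (unmasked.min() < 0.0 or unmasked.max() > 1.0):
            raise ValueError("unmasked scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Dense frame with masked cells as NA (the TSV wire format)."""
        values = self.scores.copy()
        values[self.mask] = np.nan
        return pd.DataFrame(values, index=self.patient_ids, columns=self.disease_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="patient_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "PredictionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="patient_id", na_values="NA")
        scores = frame.to_numpy(dtype=float)
        mask = np.isnan(scores)
        scores = np.nan_to_num(scores)
        return cls(scores, mask, frame.index.to_numpy(dtype=object),
                   frame.columns.to_numpy(dtype=object))


def _disease_seed(random_state: int, disease_id: str) -> int:
    # per-disease seed depends only on (random_state, disease id), so removing
    # one disease never perturbs another's forest
    return int(
        np.random.SeedSequence(
            [random_state, zlib.crc32(str(disease_id).encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


class OneVsAllDiseaseClassifier(BaseEstimator):
    """One independent random forest per disease.

    Parameters
    ----------
    n_trees : int, default 100
        Trees per forest.
    random_state : int, default 0
        Base seed; each disease's forest gets a seed derived from it and the
        disease identifier.
    exclude_prior_negatives : bool, default False
        If True, patients with a pre-split diagnosis of disease d are dropped
        from d's training set instead of serving as negatives.
    """

    def __init__(
        self,
        n_trees: int = 100,
        random_state: int = 0,
        exclude_prior_negatives: bool = False,
        n_jobs: int = 1,
    ):
        self.n_trees = n_trees
        self.random_state = random_state
        self.exclude_prior_negatives = exclude_prior_negatives
        self.n_jobs = n_jobs

    def fit(self, X, y: DiseaseLabelMatrix):
        X = check_array(X, accept_sparse="csr")
        if X.shape[0] != y.labels.shape[0]:
            raise ValueError("feature rows do not align with label rows")
        self.estimators_: dict[str, RandomForestClassifier] = {}
        for j, disease in enumerate(y.disease_ids):
            labels = y.labels[:, j]
            rows = ~y.prior[:, j] if self.exclude_prior_negatives else slice(None)
            sub_labels = labels[rows]
            classes = np.unique(sub_labels)
            if len(classes) < 2:
                state = "positive" if classes.size and classes[0] else "negative"
                raise ValueError(
                    f"disease {disease!r} has only {state} training patients; "
                    "apply select_diseases first"
                )
            forest = RandomForestClassifier(
                n_estimators=self.n_trees,
                random_state=_disease_seed(self.random_state, disease),
                n_jobs=self.n_jobs,
            )
            forest.fit(X[rows], sub_labels.astype(int))
            self.estimators_[disease] = forest
        self.disease_ids_ = np.asarray(y.disease_ids, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per (patient, disease); no mask applied."""
        check_is_fitted(self, "estimators_")
        X = check_array(X, accept_sparse="csr")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got {X.shape[1]}"
            )
        out = np.empty((X.shape[0], len(self.disease_ids_)))
        for j, disease in enumerate(self.disease_ids_):
            forest = self.estimators_[disease]
            proba = forest.predict_proba(X)
            pos = int(np.flatnonzero(forest.classes_ == 1)[0])
            out[:, j] = proba[:, pos]
        return out


def fit_one_vs_all(
    features: np.ndarray,
    train_labels: DiseaseLabelMatrix,
    n_trees: int = 100,
    seed: int = 0,
    exclude_prior_negatives: bool = False,
) -> OneVsAllDiseaseClassifier:
    """Fit one forest per disease over a representation."""
    clf = OneVsAllDiseaseClassifier(
        n_trees=n_trees,
        random_state=seed,
        exclude_prior_negatives=exclude_prior_negatives,
    )
    return clf.fit(features, train_labels)


def predict_probabilities(
    ensemble: OneVsAllDiseaseClassifier,
    features: np.ndarray,
    patient_ids,
) -> PredictionMatrix:
    """Score every patient against every disease; no mask applied yet."""
    scores = ensemble.predict_proba(features)
    return PredictionMatrix(
        scores=scores,
        mask=np.zeros_like(scores, dtype=bool),
        patient_ids=np.asarray(list(patient_ids), dtype=object),
        disease_ids=ensemble.disease_ids_,
    )


def mask_prior_diagnoses(
    preds: PredictionMatrix, prior: np.ndarray
) -> PredictionMatrix:
    """Mark cells with a pre-split diagnosis as masked (novel diseases only)."""
    prior = np.asarray(prior, dtype=bool)
    if prior.shape != preds.scores.shape:
        raise ValueError(
            f"prior shape {prior.shape} does not match scores {preds.scores.shape}"
        )
    return PredictionMatrix(
        scores=preds.scores,
        mask=preds.mask | prior,
        patient_ids=preds.patient_ids,
        disease_ids=preds.disease_ids,
    )
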