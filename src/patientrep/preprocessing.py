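"""Raw-representation preprocessing.

Turns a sparse descriptor count matrix into the "raw" patient
representation that feeds every feature learner: descriptors present in
too many or too few patients are dropped, the remaining counts are scaled
into [0, 1] by a zero-preserving division by the per-descriptor maximum,
and per-note topic multinomials (when present) are averaged into one topic
vector per patient.  Filter and scaler follow the scikit-learn
fit/transform contract so they can be fit on the feature-learning training
patients and frozen for held-out patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import PatientMatrix


def _column_support(X) -> np.ndarray:
    """Number of patients with a non-zero entry, per column."""
    if sp.issparse(X):
        return np.asarray((X != 0).sum(axis=0)).ravel()
    return np.count_nonzero(np.asarray(X), axis=0)


class DescriptorPrevalenceFilter(TransformerMixin, BaseEstimator):
    """Drop descriptors that are near-universal or near-absent.

    A column is retained iff ``min_patients <= support <= max_prevalence * N``
    where support counts patients with a non-zero entry and N is the number
    of training patients.  Ubiquitous descriptors (routine codes recorded
    for almost everyone) carry no discriminative signal; ultra-rare ones are
    noise for the representation learners.

    Parameters
    ----------
    max_prevalence : float, default 0.8
        Columns present in strictly more than this fraction of patients are
        removed.
    min_patients : int, default 5
        Columns present in strictly fewer than this many patients are
        removed.
    """

    def __init__(self, max_prevalence: float = 0.8, min_patients: int = 5):
        self.max_prevalence = max_prevalence
        self.min_patients = min_patients

    def fit(self, X, y=None):
        if not 0 < self.max_prevalence <= 1:
            raise ValueError("max_prevalence must be in (0, 1]")
        if self.min_patients < 0:
            raise ValueError("min_patients must be non-negative")
        X = check_array(X, accept_sparse="csr")
        if X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("cannot fit the prevalence filter on an empty matrix")
        support = _column_support(X)
        n = X.shape[0]
        self.support_ = support
        self.keep_mask_ = (support >= self.min_patients) & (
            support <= self.max_prevalence * n
        )
        if not self.keep_mask_.any():
            raise ValueError(
                "prevalence filter removed every descriptor; "
                "loosen max_prevalence/min_patients"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "keep_mask_")
        X = check_array(X, accept_sparse="csr")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        return X[:, self.keep_mask_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "keep_mask_")
        return self.keep_mask_


class ZeroPreservingScaler(TransformerMixin, BaseEstimator):
    """Scale counts into [0, 1] by dividing each column by its maximum.

    Unlike generic min-max scaling, dividing by the column maximum (with
    the minimum treated as 0) maps zero entries exactly to zero, keeping the
    matrix sparse.  On held-out patients, values exceeding the training
    maximum are clipped to 1.
    """

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse="csr")
        if sp.issparse(X):
            maxima = np.asarray(X.max(axis=0).todense()).ravel()
        else:
            maxima = X.max(axis=0)
        if np.any(maxima <= 0):
            bad = int(np.sum(maxima <= 0))
            raise ValueError(
                f"{bad} column(s) have no positive entries; "
                "run the prevalence filter before scaling"
            )
        self.scale_ = maxima.astype(float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X, accept_sparse="csr")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        if sp.issparse(X):
            out = X.tocsr().astype(float).copy()
            out.data /= np.take(self.scale_, out.indices)
            out.data = np.minimum(out.data, 1.0)
            return out
        return np.minimum(np.asarray(X, dtype=float) / self.scale_, 1.0)

    def inverse_transform(self, X):
        check_is_fitted(self, "scale_")
        if sp.issparse(X):
            out = X.tocsr().astype(float).copy()
            out.data *= np.take(self.scale_, out.indices)
            return out
        return np.asarray(X, dtype=float) * self.scale_


@dataclass
class ScalingStats:
    """Frozen per-descriptor maxima for reuse on held-out patients."""

    descriptor_ids: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        self.descriptor_ids = np.asarray(self.descriptor_ids, dtype=object)
        self.maxima = np.asarray(self.maxima, dtype=float)
        if len(self.descriptor_ids) != len(self.maxima):
            raise ValueError("descriptor_ids and maxima lengths differ")
        if np.any(self.maxima <= 0):
            raise ValueError("scaling maxima must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"descriptor_id": self.descriptor_ids, "max": self.maxima})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScalingStats":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame["descriptor_id"].to_numpy(), frame["max"].to_numpy())


def filter_descriptors(
    m: PatientMatrix,
    max_prevalence: float = 0.8,
    min_patients: int = 5,
    filter_: DescriptorPrevalenceFilter | None = None,
) -> tuple[PatientMatrix, list[str], DescriptorPrevalenceFilter]:
    """Apply the prevalence filter to the descriptor block of a matrix.

    Topic columns bypass the filter.  Pass a fitted ``filter_`` to reuse
    training-set support statistics on held-out patients.  Returns the
    filtered matrix, the removed descriptor ids, and the fitted filter.
    """
    desc = m.descriptor_mask
    if filter_ is None:
        filter_ = DescriptorPrevalenceFilter(max_prevalence, min_patients)
        filter_.fit(m.values[:, desc])
    keep_desc = filter_.get_support()
    keep = np.ones(m.n_columns, dtype=bool)
    keep[np.flatnonzero(desc)] = keep_desc
    removed = list(m.vocabulary[desc][~keep_desc])
    return m.select_columns(np.flatnonzero(keep)), removed, filter_


def scale_minmax(
    m: PatientMatrix, stats: ScalingStats | None = None
) -> tuple[PatientMatrix, ScalingStats]:
    """Zero-preserving [0, 1] scaling of the descriptor block.

    With ``stats=None`` the per-descriptor maxima are fit on ``m`` (every
    descriptor column must have a positive maximum, i.e. the matrix has been
    filtered); otherwise the frozen maxima are applied and out-of-range
    held-out values clip to 1.  Topic columns pass through unchanged.
    """
    desc_idx = np.flatnonzero(m.descriptor_mask)
    scaler = ZeroPreservingScaler()
    if stats is None:
        scaler.fit(m.values[:, desc_idx])
        stats = ScalingStats(m.vocabulary[desc_idx], scaler.scale_)
    else:
        if not np.array_equal(stats.descriptor_ids, m.vocabulary[desc_idx]):
            raise ValueError("scaling stats do not match the matrix vocabulary")
        scaler.scale_ = stats.maxima
        scaler.n_features_in_ = len(desc_idx)
    scaled_desc = scaler.transform(m.values[:, desc_idx])
    # reassemble preserving original column order
    out = m.values.tocsc().astype(float)
    out[:, desc_idx] = sp.csc_matrix(scaled_desc)
    return (
        PatientMatrix(out.tocsr(), m.patient_ids, m.vocabulary, m.kinds),
        stats,
    )


def average_topic_rows(
    note_topics: np.ndarray,
    note_to_patient: Sequence[str],
    patient_ids: Sequence[str],
    tol: float = 1e-6,
) -> np.ndarray:
    """Average per-note topic multinomials into one row per patient.

    Clinical notes are summarized as multinomials over topics; a patient's
    topic representation is the arithmetic mean of their note rows.
    Patients without notes get a zero row.

    Parameters
    ----------
    note_topics : array, shape (n_notes, n_topics)
        One multinomial per note; each row must sum to 1 within ``tol``.
    note_to_patient : sequence of str, length n_notes
        Owning patient of each note; must name patients in ``patient_ids``.
    patient_ids : sequence of str
        Output row order.
    """
    note_topics = np.asarray(note_topics, dtype=float)
    if note_topics.ndim != 2:
        raise ValueError("note_topics must be 2-D")
    if len(note_to_patient) != note_topics.shape[0]:
        raise ValueError("one owning patient required per note row")
    if note_topics.shape[0]:
        sums = note_topics.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            raise ValueError("every note row must sum to 1")
    patient_ids = list(patient_ids)
    index: Mapping[str, int] = {p: i for i, p in enumerate(patient_ids)}
    dangling = sorted(set(note_to_patient) - set(index))
    if dangling:
        raise ValueError(f"notes reference unknown patients: {dangling}")

    out = np.zeros((len(patient_ids), note_topics.shape[1]))
    counts = np.zeros(len(patient_ids))
    for row, pid in zip(note_topics, note_to_patient):
        i = index[pid]
        out[i] += row
        counts[i] += 1
    has_notes = counts > 0
    out[has_notes] /= counts[has_notes, None]
    return out
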