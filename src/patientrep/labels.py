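"""Future-window disease labels.

A label marks a *novel* diagnosis: disease d gets label 1 for patient p in a
window of w days iff d is first diagnosed for p at a day offset in [1, w]
and p has no pre-split-point record of d.  Re-diagnoses are never positive
labels — they are carried in the prior matrix and masked out of both
training positives and evaluation.  Windows are nested: the labels for a
shorter window are entry-wise dominated by those for a longer one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DiseaseLabelMatrix:
    """Binary novel-diagnosis labels with the prior-diagnosis mask."""

    labels: np.ndarray  # bool (n_patients, n_diseases)
    prior: np.ndarray  # bool, pre-split diagnoses
    window_days: int
    patient_ids: np.ndarray
    disease_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.prior = np.asarray(self.prior, dtype=bool)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.disease_ids = np.asarray(self.disease_ids, dtype=object)
        if self.labels.shape != self.prior.shape:
            raise ValueError("labels and prior must share a shape")
        if self.labels.shape != (len(self.patient_ids), len(self.disease_ids)):
            raise ValueError("label matrix shape does not match the id axes")
        if np.any(self.labels & self.prior):
            raise ValueError("a re-diagnosis can never be a positive label")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    @property
    def n_positives(self) -> np.ndarray:
        """Positive patients per disease."""
        return self.labels.sum(axis=0)


def _event_matrix(
    events: pd.DataFrame,
    patient_ids: np.ndarray,
    disease_ids: np.ndarray,
    what: str,
) -> np.ndarray:
    out = np.zeros((len(patient_ids), len(disease_ids)), dtype=bool)
    if len(events) == 0:
        return out
    p_index = {p: i for i, p in enumerate(patient_ids)}
    d_index = {d: j for j, d in enumerate(disease_ids)}
    unknown = sorted(set(events["disease_id"]) - set(d_index))
    if unknown:
        raise ValueError(f"unknown diseases in {what}: {unknown}")
    keep = events["patient_id"].isin(p_index)
    rows = events.loc[keep, "patient_id"].map(p_index).to_numpy(dtype=np.intp)
    cols = events.loc[keep, "disease_id"].map(d_index).to_numpy(dtype=np.intp)
    out[rows, cols] = True
    return out


def build_prior_matrix(
    histories: pd.DataFrame,
    patient_ids: Sequence[str],
    disease_ids: Sequence[str],
) -> np.ndarray:
    """Binary patient x disease matrix of pre-split-point diagnoses."""
    patient_ids = np.asarray(list(patient_ids), dtype=object)
    disease_ids = np.asarray(list(disease_ids), dtype=object)
    return _event_matrix(histories, patient_ids, disease_ids, "histories")


def build_label_matrix(
    events: pd.DataFrame,
    histories: pd.DataFrame,
    window_days: int,
    disease_ids: Sequence[str],
    patient_ids: Sequence[str],
) -> DiseaseLabelMatrix:
    """Novel-diagnosis labels for one future window.

    Parameters
    ----------
    events : DataFrame (patient_id, disease_id, day_offset >= 1)
        Future diagnoses, dated in days after the split-point.
    histories : DataFrame (patient_id, disease_id, day_offset < 0)
        Pre-split diagnoses; any disease diagnosed here is masked.
    window_days : int
        Label horizon; only events with day_offset in [1, window_days] count.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    patient_ids = np.asarray(list(patient_ids), dtype=object)
    disease_ids = np.asarray(list(disease_ids), dtype=object)
    prior = _event_matrix(histories, patient_ids, disease_ids, "histories")
    in_window = events[
        (events["day_offset"] >= 1) & (events["day_offset"] <= window_days)
    ] if len(events) else events
    hits = _event_matrix(in_window, patient_ids, disease_ids, "future events")
    return DiseaseLabelMatrix(
        labels=hits & ~prior,
        prior=prior,
        window_days=window_days,
        patient_ids=patient_ids,
        disease_ids=disease_ids,
    )


def select_diseases(
    train_labels: DiseaseLabelMatrix, min_positive: int = 10
) -> np.ndarray:
    """Diseases with at least ``min_positive`` positive training patients.

    Keeps the input order.  Classifiers for rarer diseases would be fit on
    too few positives to be meaningful.
    """
    if train_labels.labels.size == 0:
        raise ValueError("empty label matrix")
    keep = train_labels.n_positives >= min_positive
    if not keep.any():
        raise ValueError(
            f"no disease has >= {min_positive} positive training patients"
        )
    return train_labels.disease_ids[keep]


def restrict_diseases(
    matrix: DiseaseLabelMatrix, disease_ids: Sequence[str]
) -> DiseaseLabelMatrix:
    """Project a label matrix onto a disease sub-vocabulary, keeping order."""
    disease_ids = np.asarray(list(disease_ids), dtype=object)
    index = {d: j for j, d in enumerate(matrix.disease_ids)}
    missing = [d for d in disease_ids if d not in index]
    if missing:
        raise ValueError(f"diseases not in the matrix: {missing}")
    cols = np.array([index[d] for d in disease_ids], dtype=np.intp)
    return DiseaseLabelMatrix(
        labels=matrix.labels[:, cols],
        prior=matrix.prior[:, cols],
        window_days=matrix.window_days,
        patient_ids=matrix.patient_ids,
        disease_ids=disease_ids,
    )
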