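"""Sparse patient x clinical-descriptor matrices.

A :class:`PatientMatrix` pairs a sparse non-negative matrix with aligned
patient identifiers and a descriptor vocabulary.  Descriptor columns hold
occurrence counts of normalized clinical codes (diagnoses, medications,
procedures, lab tests); optional topic columns hold per-patient topic
proportions in [0, 1] and are flagged with kind ``"topic"`` so that
prevalence filtering and count scaling can bypass them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

DESCRIPTOR_KIND = "descriptor"
TOPIC_KIND = "topic"


@dataclass
class PatientMatrix:
    """Sparse non-negative patient x descriptor matrix with aligned metadata.

    Parameters
    ----------
    values : scipy.sparse matrix, shape (n_patients, n_columns)
        Non-negative counts (descriptor columns) and/or proportions
        (topic columns).  Stored as CSR.
    patient_ids : sequence of str
        Unique row identifiers.
    vocabulary : sequence of str
        Column identifiers, one per column.
    kinds : sequence of str, optional
        Per-column kind, ``"descriptor"`` or ``"topic"``.  Defaults to all
        descriptor.
    """

    values: sp.spmatrix
    patient_ids: np.ndarray
    vocabulary: np.ndarray
    kinds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.vocabulary = np.asarray(self.vocabulary, dtype=object)
        if self.kinds is None:
            self.kinds = np.full(len(self.vocabulary), DESCRIPTOR_KIND, dtype=object)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.values.shape[0] != len(self.patient_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.patient_ids)} patient ids"
            )
        if self.values.shape[1] != len(self.vocabulary):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.vocabulary)} vocabulary entries"
            )
        if len(self.kinds) != len(self.vocabulary):
            raise ValueError("kinds and vocabulary lengths differ")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("patient_ids are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("patient matrix has negative entries")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def descriptor_mask(self) -> np.ndarray:
        return self.kinds == DESCRIPTOR_KIND

    @property
    def topic_mask(self) -> np.ndarray:
        return self.kinds == TOPIC_KIND

    def select_rows(self, indices: np.ndarray) -> "PatientMatrix":
        return PatientMatrix(
            self.values[indices], self.patient_ids[indices], self.vocabulary, self.kinds
        )

    def select_columns(self, indices: np.ndarray) -> "PatientMatrix":
        return PatientMatrix(
            self.values[:, indices],
            self.patient_ids,
            self.vocabulary[indices],
            self.kinds[indices],
        )

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def equals(self, other: "PatientMatrix") -> bool:
        return (
            self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
            and np.array_equal(self.patient_ids, other.patient_ids)
            and np.array_equal(self.vocabulary, other.vocabulary)
            and np.array_equal(self.kinds, other.kinds)
        )


def build_count_matrix(
    events: pd.DataFrame | Iterable[tuple[str, str]],
    vocabulary: Sequence[str],
    patient_ids: Sequence[str] | None = None,
) -> PatientMatrix:
    """Tally descriptor occurrences per patient into a sparse count matrix.

    Each event names one patient and one descriptor; entry (p, d) of the
    result is the number of events pairing them.  Events are assumed to
    predate the split-point (history only).

    Parameters
    ----------
    events : DataFrame with columns (patient_id, descriptor_id), or iterable
        of (patient_id, descriptor_id) pairs.  May be empty.
    vocabulary : sequence of str
        Allowed descriptors, in output column order.  Events naming a
        descriptor outside it raise ``ValueError`` listing the offenders.
    patient_ids : sequence of str, optional
        Row order.  Defaults to patients in order of first appearance.
    """
    if not isinstance(events, pd.DataFrame):
        events = pd.DataFrame(list(events), columns=["patient_id", "descriptor_id"])
    elif not {"patient_id", "descriptor_id"} <= set(events.columns):
        raise ValueError("events need patient_id and descriptor_id columns")

    vocabulary = np.asarray(list(vocabulary), dtype=object)
    vocab_index = {d: j for j, d in enumerate(vocabulary)}
    unknown = sorted(set(events["descriptor_id"]) - set(vocab_index))
    if unknown:
        raise ValueError(f"unknown descriptors in event stream: {unknown}")

    if patient_ids is None:
        patient_ids = pd.unique(events["patient_id"])
    patient_ids = np.asarray(list(patient_ids), dtype=object)
    row_index = {p: i for i, p in enumerate(patient_ids)}
    missing = sorted(set(events["patient_id"]) - set(row_index))
    if missing:
        raise ValueError(f"events name patients outside patient_ids: {missing}")

    rows = events["patient_id"].map(row_index).to_numpy(dtype=np.intp)
    cols = events["descriptor_id"].map(vocab_index).to_numpy(dtype=np.intp)
    values = sp.coo_matrix(
        (np.ones(len(events)), (rows, cols)),
        shape=(len(patient_ids), len(vocabulary)),
    ).tocsr()
    return PatientMatrix(values, patient_ids, vocabulary)
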