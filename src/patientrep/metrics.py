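"""Evaluation protocols for future-disease prediction.

Two complementary views:

* **by disease** — for each disease, scores of all evaluable test patients
  (those without a prior diagnosis of it) are graded with AUC-ROC and, at a
  fixed probability threshold (default 0.6), accuracy and F-score; the
  summary is the unweighted (macro) mean over diseases.
* **by patient** — predictions above the threshold are treated as disease
  tags and graded as ranked retrieval per patient: precision-at-k for
  k = 1, 3, 5 and R-precision (precision over the top R tags, R = the
  patient's number of true novel diagnoses in the window), averaged over
  patients with at least one true diagnosis in the window, alongside the
  theoretical upper bound min(R, k)/k that a perfect tagger would reach.

AUC follows the Mann-Whitney convention (ties get half credit), so a
constant score vector scores exactly 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .classify import PredictionMatrix
from .labels import DiseaseLabelMatrix


def roc_auc(scores, labels, name: str | None = None) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties at half credit)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    if labels.all() or not labels.any():
        what = f" for {name}" if name else ""
        raise ValueError(f"AUC undefined{what}: only one class present")
    return float(roc_auc_score(labels, scores))


class ThresholdMetrics(NamedTuple):
    accuracy: float
    precision: float
    recall: float
    f_score: float


def threshold_metrics(
    scores, labels, threshold: float = 0.6, inclusive: bool = True
) -> ThresholdMetrics:
    """Confusion-matrix metrics at a fixed probability threshold.

    A score of exactly ``threshold`` counts as positive when ``inclusive``
    (the default).  Precision (and hence F) is reported as 0 when there are
    no predicted positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size == 0:
        raise ValueError("cannot compute threshold metrics on empty input")
    pred = scores >= threshold if inclusive else scores > threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    accuracy = (tp + tn) / scores.size
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return ThresholdMetrics(accuracy, precision, recall, f_score)


def _ranked_tags(
    scores_row: np.ndarray,
    mask_row: np.ndarray,
    threshold: float,
    inclusive: bool = True,
) -> np.ndarray:
    """Candidate disease indices ranked by descending score.

    Only unmasked cells clearing the tagging threshold are candidates; ties
    break by ascending disease index for deterministic reports.
    """
    above = scores_row >= threshold if inclusive else scores_row > threshold
    cand = np.flatnonzero(above & ~mask_row)
    return cand[np.lexsort((cand, -scores_row[cand]))]


def _evaluated_patients(preds: PredictionMatrix, labels: DiseaseLabelMatrix) -> np.ndarray:
    """Patients gradeable at the patient level: >= 1 true novel diagnosis in
    the window and >= 1 unmasked candidate cell."""
    if preds.scores.shape != labels.labels.shape:
        raise ValueError("prediction and label matrices must align")
    has_truth = labels.labels.any(axis=1)
    has_candidates = (~preds.mask).any(axis=1)
    return np.flatnonzero(has_truth & has_candidates)


def precision_at_k(
    preds: PredictionMatrix,
    labels: DiseaseLabelMatrix,
    k: int,
    threshold: float = 0.6,
) -> float:
    """Mean over patients of |top-k tags that are true| / k.

    The denominator stays k even when fewer than k tags clear the threshold,
    matching the fixed-k convention of the upper-bound model.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = _evaluated_patients(preds, labels)
    if rows.size == 0:
        raise ValueError("no patient has a true in-window diagnosis to grade")
    vals = np.empty(rows.size)
    for i, p in enumerate(rows):
        ranked = _ranked_tags(preds.scores[p], preds.mask[p], threshold)[:k]
        vals[i] = labels.labels[p, ranked].sum() / k
    return float(vals.mean())


def r_precision(
    preds: PredictionMatrix,
    labels: DiseaseLabelMatrix,
    threshold: float = 0.6,
    keep_below_threshold: bool = False,
) -> float:
    """Mean per-patient precision over the top-R tags, R = #true diagnoses.

    By default tags below the threshold are excluded from the ranking (they
    were never asserted); ``keep_below_threshold=True`` lets low-score
    predictions occupy ranks instead.
    """
    rows = _evaluated_patients(preds, labels)
    if rows.size == 0:
        raise ValueError("no patient has a true in-window diagnosis to grade")
    eff_threshold = -np.inf if keep_below_threshold else threshold
    vals = np.empty(rows.size)
    for i, p in enumerate(rows):
        r = int(labels.labels[p].sum())
        ranked = _ranked_tags(preds.scores[p], preds.mask[p], eff_threshold)[:r]
        vals[i] = labels.labels[p, ranked].sum() / r
    return float(vals.mean())


def upper_bound_precision_at_k(labels: DiseaseLabelMatrix, k: int) -> float:
    """Best achievable Prec@k: a tagger assigning every true diagnosis scores
    min(R, k)/k per patient."""
    if k < 1:
        raise ValueError("k must be >= 1")
    r = labels.labels.sum(axis=1)
    r = r[r >= 1]
    if r.size == 0:
        raise ValueError("no patient has a true in-window diagnosis to grade")
    return float(np.mean(np.minimum(r, k) / k))


@dataclass
class EvaluationReport:
    """Per-disease and per-patient metric tables with macro summaries."""

    by_disease: pd.DataFrame
    by_patient: pd.DataFrame
    macro: dict[str, float]
    threshold: float
    average: str = "macro"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "average": self.average,
            "macro": self.macro,
            "by_disease": self.by_disease.to_dict(orient="records"),
            "by_patient": self.by_patient.to_dict(orient="records"),
            "warnings": list(self.warnings),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        data = json.loads(Path(path).read_text())
        return cls(
            by_disease=pd.DataFrame(data["by_disease"]),
            by_patient=pd.DataFrame(data["by_patient"]),
            macro=data["macro"],
            threshold=data["threshold"],
            average=data.get("average", "macro"),
            warnings=data.get("warnings", []),
        )

    def to_tsv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.by_disease.to_csv(directory / "by_disease.tsv", sep="\t", index=False)
        self.by_patient.to_csv(directory / "by_patient.tsv", sep="\t", index=False)


def evaluate(
    preds: PredictionMatrix,
    label_windows: Sequence[DiseaseLabelMatrix] | DiseaseLabelMatrix,
    threshold: float = 0.6,
    ks: Iterable[int] = (1, 3, 5),
    average: str = "macro",
) -> EvaluationReport:
    """Full evaluation report over one or more temporal windows.

    Disease-level metrics are computed on the largest window; patient-level
    tagging metrics are reported per window together with the matching
    upper bounds.  Diseases whose evaluable population lacks one of the two
    classes are excluded from the summary and listed in ``warnings``.
    ``average="micro"`` pools every unmasked (patient, disease) cell into a
    single vector instead of averaging per-disease rows.
    """
    if isinstance(label_windows, DiseaseLabelMatrix):
        label_windows = [label_windows]
    label_windows = sorted(label_windows, key=lambda m: m.window_days)
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    widest = label_windows[-1]
    if preds.scores.shape != widest.labels.shape:
        raise ValueError("prediction and label matrices must align")
    if not np.array_equal(preds.disease_ids, widest.disease_ids):
        raise ValueError("prediction and label disease vocabularies differ")

    ks = sorted(int(k) for k in ks)
    rows = []
    warnings: list[str] = []
    for j, disease in enumerate(preds.disease_ids):
        pop = np.flatnonzero(~preds.mask[:, j])
        y = widest.labels[pop, j]
        s = preds.scores[pop, j]
        if y.size == 0 or y.all() or not y.any():
            warnings.append(f"{disease}: single-class evaluable population, skipped")
            continue
        tm = threshold_metrics(s, y, threshold)
        rows.append(
            {
                "disease_id": disease,
                "n_eval_patients": int(y.size),
                "n_positive": int(y.sum()),
                "auc": roc_auc(s, y, name=disease),
                "accuracy": tm.accuracy,
                "f_score": tm.f_score,
            }
        )
    if not rows:
        raise ValueError("no disease has an evaluable two-class population")
    by_disease = pd.DataFrame(rows)

    if average == "macro":
        macro = {
            "auc": float(by_disease["auc"].mean()),
            "accuracy": float(by_disease["accuracy"].mean()),
            "f_score": float(by_disease["f_score"].mean()),
        }
    else:
        flat_mask = ~preds.mask.ravel()
        s = preds.scores.ravel()[flat_mask]
        y = widest.labels.ravel()[flat_mask]
        tm = threshold_metrics(s, y, threshold)
        macro = {
            "auc": roc_auc(s, y),
            "accuracy": tm.accuracy,
            "f_score": tm.f_score,
        }
    macro["n_diseases"] = float(len(by_disease))

    patient_rows = []
    for window in label_windows:
        evaluated = _evaluated_patients(preds, window)
        row: dict[str, float] = {
            "window_days": window.window_days,
            "n_patients": int(evaluated.size),
        }
        for k in ks:
            row[f"prec_at_{k}"] = precision_at_k(preds, window, k, threshold)
            row[f"uppbnd_prec_at_{k}"] = upper_bound_precision_at_k(window, k)
        row["r_precision"] = r_precision(preds, window, threshold)
        patient_rows.append(row)
    by_patient = pd.DataFrame(patient_rows)

    return EvaluationReport(
        by_disease=by_disease,
        by_patient=by_patient,
        macro=macro,
        threshold=threshold,
        average=average,
        warnings=warnings,
    )
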