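"""Brute-force reference implementations used to check the fast metrics.

These enumerate pairs and rankings directly from the definitions and are
deliberately independent of the package's implementations.
"""

from __future__ import annotations

import numpy as np


def auc_by_pair_enumeration(scores, labels) -> float:
    """P(score+ > score-) + 0.5 P(tie), over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _ranked(scores_row, mask_row, threshold):
    """Candidate indices above threshold, by descending score then index."""
    cand = [
        j
        for j in range(len(scores_row))
        if not mask_row[j] and scores_row[j] >= threshold
    ]
    return sorted(cand, key=lambda j: (-scores_row[j], j))


def prec_at_k_by_enumeration(scores, mask, labels, k, threshold=0.6) -> float:
    vals = []
    for i in range(scores.shape[0]):
        if not labels[i].any() or mask[i].all():
            continue
        top = _ranked(scores[i], mask[i], threshold)[:k]
        vals.append(sum(labels[i, j] for j in top) / k)
    return float(np.mean(vals))


def r_precision_by_enumeration(scores, mask, labels, threshold=0.6) -> float:
    vals = []
    for i in range(scores.shape[0]):
        r = int(labels[i].sum())
        if r == 0 or mask[i].all():
            continue
        top = _ranked(scores[i], mask[i], threshold)[:r]
        vals.append(sum(labels[i, j] for j in top) / r)
    return float(np.mean(vals))


def upper_bound_by_enumeration(labels, k) -> float:
    vals = []
    for i in range(labels.shape[0]):
        r = int(labels[i].sum())
        if r == 0:
            continue
        vals.append(min(r, k) / k)
    return float(np.mean(vals))


def random_tagging_instance(rng, n_patients=10, n_diseases=8):
    """One random evaluation instance with at least one gradeable patient."""
    while True:
        scores = np.round(rng.random((n_patients, n_diseases)), 2)
        prior = rng.random((n_patients, n_diseases)) < 0.2
        labels = (rng.random((n_patients, n_diseases)) < 0.25) & ~prior
        if labels.any(axis=1).any():
            return scores, prior, labels
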