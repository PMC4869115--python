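"""Synthetic EHR cohort generation.

Real EHR warehouses are private, so the pipeline is exercised on simulated
cohorts that reproduce the statistical structure it assumes:

* each patient carries a handful of latent binary conditions (chronic
  states the record reflects only indirectly);
* descriptor counts are Poisson with log-linear intensity in the latents —
  every latent elevates a sparse random set of "marker" descriptors — which
  yields sparse, correlated, overdispersed counts;
* an optional topic block appends per-patient topic proportions drawn from
  a Dirichlet whose concentration shifts with the latents;
* time is measured in integer day offsets from the split-point (history
  strictly negative, future events >= 1), so no calendar parsing is needed;
* future-window disease labels are Bernoulli with log-odds linear in the
  latents for "main-effect" diseases and, for a configurable fraction of
  diseases, dependent on a pairwise latent interaction (an exclusive-or
  term) — the nonlinearity that a deep representation can exploit and a
  purely linear one cannot.

Ground-truth latents are stored on the cohort for testing but are never
consumed by the pipeline itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.special import expit, logit

from .matrix import DESCRIPTOR_KIND, TOPIC_KIND, PatientMatrix


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_patients, n_descriptors, n_diseases : int
        Cohort dimensions.
    n_topics : int
        Topic-proportion columns appended after the descriptors (0 = none).
    n_latent : int
        Latent binary conditions per patient.
    latent_prevalence : float
        Bernoulli rate of each latent condition.
    mean_records : float
        Baseline expected number of descriptor records per patient (before
        the latent-driven boost and the per-patient intensity multiplier).
    signal_strength : float
        Scale of the latent effect on disease log-odds; 0 gives labels that
        are pure noise.
    interaction_frac : float
        Fraction of diseases whose log-odds depend on a pairwise latent
        interaction instead of a linear term.
    prior_rate : float
        Marginal probability of a pre-split diagnosis per (patient, disease);
        generates the re-diagnosis cases the evaluation must discard.
    window_days : list of int
        Future evaluation windows; events are dated uniformly inside the
        largest one so smaller windows are prefixes.
    seed : int
        Drives every random draw; identical config + seed gives a
        bit-identical cohort.
    """

    n_patients: int = 2000
    n_descriptors: int = 300
    n_topics: int = 0
    n_latent: int = 12
    n_diseases: int = 20
    latent_prevalence: float = 0.4
    mean_records: float = 150.0
    signal_strength: float = 3.0
    interaction_frac: float = 0.5
    prior_rate: float = 0.08
    window_days: list[int] = field(default_factory=lambda: [30, 60, 90, 180])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("n_descriptors", "n_latent", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_topics < 0:
            raise ValueError("n_topics must be >= 0")
        for name in ("latent_prevalence", "interaction_frac", "prior_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_records <= 0:
            raise ValueError("mean_records must be positive")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if not self.window_days or any(w < 1 for w in self.window_days):
            raise ValueError("window_days must be a non-empty list of positive ints")
        self.window_days = sorted(int(w) for w in self.window_days)


@dataclass
class SyntheticCohort:
    """One simulated cohort: counts, histories, future events, ground truth."""

    counts: PatientMatrix
    histories: pd.DataFrame  # patient_id, disease_id, day_offset (< 0)
    future_events: pd.DataFrame  # patient_id, disease_id, day_offset (>= 1)
    latents: np.ndarray  # (n_patients, n_latent), test-only ground truth
    record_counts: np.ndarray  # per-patient pre-split record totals
    disease_ids: np.ndarray
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if len(self.future_events) and self.future_events["day_offset"].min() < 1:
            raise ValueError("future events must be dated strictly after day 0")
        if len(self.histories) and self.histories["day_offset"].max() > -1:
            raise ValueError("history events must be dated strictly before day 0")

    @property
    def patient_ids(self) -> np.ndarray:
        return self.counts.patient_ids


@dataclass
class CohortSplits:
    """Disjoint patient index sets for the four pipeline roles."""

    feature_train: np.ndarray
    classifier_train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        all_idx = np.concatenate(
            [self.feature_train, self.classifier_train, self.validation, self.test]
        )
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split sets overlap")


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {"patient_id": pd.Series(dtype=object),
         "disease_id": pd.Series(dtype=object),
         "day_offset": pd.Series(dtype=np.int64)}
    )


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Sample one synthetic cohort from the generative model above."""
    rng = np.random.default_rng(config.seed)
    P, D, L = config.n_patients, config.n_descriptors, config.n_latent
    T, K = config.n_topics, config.n_diseases

    patient_ids = np.array([f"P{i:06d}" for i in range(P)], dtype=object)
    descriptor_ids = [f"D{j:04d}" for j in range(D)]
    topic_ids = [f"T{j:03d}" for j in range(T)]
    disease_ids = np.array([f"DIS{j:03d}" for j in range(K)], dtype=object)

    # latent binary conditions
    H = (rng.random((P, L)) < config.latent_prevalence).astype(np.int8)

    # descriptor intensities: skewed baseline rates plus overlapping weak
    # latent markers (half the vocabulary per latent).  Spreading each latent
    # over many individually weak markers mirrors the redundancy of clinical
    # coding: no single descriptor identifies a condition, their aggregate
    # does.  Record volume varies through the latent burden itself (patients
    # with more conditions accumulate more records).
    base_weight = rng.gamma(0.5, size=D)
    base_rate = config.mean_records * base_weight / base_weight.sum()
    n_markers = max(4, D // 2)
    A = np.zeros((L, D))
    for k in range(L):
        markers = rng.choice(D, size=n_markers, replace=False)
        half = n_markers // 2
        # each condition elevates half its markers and suppresses the rest
        # (displaced routine care), so descriptors are signed mixtures
        A[k, markers[:half]] = rng.uniform(0.3, 0.7, size=half)
        A[k, markers[half:]] = rng.uniform(-0.7, -0.3, size=n_markers - half)
    lam = base_rate[None, :] * np.exp(H @ A)
    counts = rng.poisson(lam).astype(np.int64)
    record_counts = counts.sum(axis=1)

    blocks = [sp.csr_matrix(counts.astype(float))]
    kinds = [DESCRIPTOR_KIND] * D
    if T > 0:
        topic_load = np.zeros((L, T))
        for k in range(L):
            boosted = rng.choice(T, size=min(2, T), replace=False)
            topic_load[k, boosted] = rng.uniform(1.0, 3.0, size=len(boosted))
        alpha = 0.3 + H @ topic_load
        gams = rng.gamma(alpha) if P else np.zeros((0, T))
        topics = gams / gams.sum(axis=1, keepdims=True) if P else gams
        blocks.append(sp.csr_matrix(topics))
        kinds += [TOPIC_KIND] * T
    values = sp.hstack(blocks, format="csr") if len(blocks) > 1 else blocks[0]
    matrix = PatientMatrix(
        values, patient_ids, np.array(descriptor_ids + topic_ids, dtype=object),
        np.array(kinds, dtype=object),
    )

    # pre-split diagnosis histories (drive the re-diagnosis masking)
    prior = rng.random((P, K)) < config.prior_rate
    pi, di = np.nonzero(prior)
    histories = pd.DataFrame(
        {
            "patient_id": patient_ids[pi],
            "disease_id": disease_ids[di],
            "day_offset": -rng.integers(1, 731, size=len(pi)),
        }
    ) if len(pi) else _empty_events()

    # future-window diseases: log-odds linear or exclusive-or in the latents
    n_interaction = int(round(config.interaction_frac * K))
    interaction = np.zeros(K, dtype=bool)
    interaction[rng.choice(K, size=n_interaction, replace=False)] = True
    base_logit = logit(rng.uniform(0.08, 0.18, size=K))
    effect = np.zeros((P, K))
    s = config.signal_strength
    for j in range(K):
        a, b = rng.choice(L, size=2, replace=False)
        if interaction[j]:
            # XOR(h_a, h_b) = h_a + h_b - 2 h_a h_b: carries a pairwise product
            effect[:, j] = s * (H[:, a] + H[:, b] - 2.0 * H[:, a] * H[:, b])
        else:
            effect[:, j] = s * 0.5 * (H[:, a] + H[:, b])
    prob = expit(base_logit[None, :] + effect)
    occurs = rng.random((P, K)) < prob
    max_window = max(config.window_days)
    pi, di = np.nonzero(occurs)
    future_events = pd.DataFrame(
        {
            "patient_id": patient_ids[pi],
            "disease_id": disease_ids[di],
            "day_offset": rng.integers(1, max_window + 1, size=len(pi)),
        }
    ) if len(pi) else _empty_events()

    return SyntheticCohort(
        counts=matrix,
        histories=histories,
        future_events=future_events,
        latents=H,
        record_counts=record_counts,
        disease_ids=disease_ids,
        config=config,
    )


def split_cohort(
    cohort: SyntheticCohort,
    min_records_featlearn: int = 5,
    min_records_test: int = 10,
    n_classifier_train: int = 400,
    n_validation: int = 100,
    n_test: int | None = None,
    seed: int = 0,
) -> CohortSplits:
    """Partition patients into disjoint feature-learning / classifier /
    validation / test sets.

    Test and validation patients need at least ``min_records_test`` pre-split
    records and at least one future diagnosis (so predictions can be graded);
    training patients need at least ``min_records_featlearn`` records.  With
    ``n_test=None`` the test set takes every remaining eligible patient,
    mirroring a hold-back design; passing an explicit size leaves more
    patients for unsupervised feature learning.
    """
    if min_records_featlearn < 1 or min_records_test < 1:
        raise ValueError("record thresholds must be >= 1")
    rng = np.random.default_rng(seed)
    n = cohort.counts.n_patients
    has_future = np.zeros(n, dtype=bool)
    if len(cohort.future_events):
        idx = {p: i for i, p in enumerate(cohort.patient_ids)}
        has_future[[idx[p] for p in cohort.future_events["patient_id"].unique()]] = True

    eligible_test = np.flatnonzero((cohort.record_counts >= min_records_test) & has_future)
    rng.shuffle(eligible_test)
    n_test_eff = len(eligible_test) - n_validation if n_test is None else n_test
    if len(eligible_test) < n_validation + max(n_test_eff, 1):
        raise ValueError(
            f"test/validation pool too small: {len(eligible_test)} eligible patients "
            f"for n_validation={n_validation}, n_test={n_test_eff}"
        )
    validation = eligible_test[:n_validation]
    test = eligible_test[n_validation : n_validation + n_test_eff]

    held = np.zeros(n, dtype=bool)
    held[validation] = True
    held[test] = True
    trainable = np.flatnonzero((cohort.record_counts >= min_records_featlearn) & ~held)
    if len(trainable) < n_classifier_train + 1:
        raise ValueError(
            f"training pool too small: {len(trainable)} eligible patients for "
            f"n_classifier_train={n_classifier_train} plus feature learning"
        )
    rng.shuffle(trainable)
    classifier_train = trainable[:n_classifier_train]
    feature_train = trainable[n_classifier_train:]
    return CohortSplits(
        feature_train=np.sort(feature_train),
        classifier_train=np.sort(classifier_train),
        validation=np.sort(validation),
        test=np.sort(test),
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, int]:
    """Write a cohort to ``directory``; returns a {file: rows} manifest.

    Formats: MatrixMarket for the count matrix, TSV for patients,
    vocabulary, events and latents, JSON for the config echo.  The written
    form round-trips exactly through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(directory / "counts.mtx", cohort.counts.values, precision=17)
    pd.DataFrame(
        {"patient_id": cohort.patient_ids, "n_records": cohort.record_counts}
    ).to_csv(directory / "patients.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"descriptor_id": cohort.counts.vocabulary, "kind": cohort.counts.kinds}
    ).to_csv(directory / "vocabulary.tsv", sep="\t", index=False)
    events = pd.concat([cohort.histories, cohort.future_events], ignore_index=True)
    events.to_csv(directory / "events.tsv", sep="\t", index=False)
    pd.DataFrame(
        cohort.latents,
        columns=[f"L{j:02d}" for j in range(cohort.latents.shape[1])],
    ).assign(patient_id=cohort.patient_ids)[
        ["patient_id"] + [f"L{j:02d}" for j in range(cohort.latents.shape[1])]
    ].to_csv(directory / "latents.tsv", sep="\t", index=False)
    (directory / "config.json").write_text(
        json.dumps(asdict(cohort.config), indent=2)
    )
    (directory / "diseases.tsv").write_text(
        "disease_id\n" + "".join(f"{d}\n" for d in cohort.disease_ids)
    )
    return {
        "counts.mtx": cohort.counts.n_patients,
        "patients.tsv": cohort.counts.n_patients,
        "vocabulary.tsv": cohort.counts.n_columns,
        "events.tsv": len(events),
        "latents.tsv": cohort.counts.n_patients,
        "diseases.tsv": len(cohort.disease_ids),
        "config.json": 1,
    }


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    config = GeneratorConfig(**json.loads((directory / "config.json").read_text()))
    values = sp.csr_matrix(mmread(directory / "counts.mtx"))
    patients = pd.read_csv(directory / "patients.tsv", sep="\t")
    vocab = pd.read_csv(directory / "vocabulary.tsv", sep="\t")
    events = pd.read_csv(
        directory / "events.tsv", sep="\t",
        dtype={"patient_id": object, "disease_id": object, "day_offset": np.int64},
    )
    if len(events) == 0:
        events = _empty_events()
    latents_frame = pd.read_csv(directory / "latents.tsv", sep="\t")
    disease_ids = pd.read_csv(directory / "diseases.tsv", sep="\t")["disease_id"]
    matrix = PatientMatrix(
        values,
        patients["patient_id"].astype(object).to_numpy(),
        vocab["descriptor_id"].astype(object).to_numpy(),
        vocab["kind"].astype(object).to_numpy(),
    )
    histories = events[events["day_offset"] < 0].reset_index(drop=True)
    future = events[events["day_offset"] >= 1].reset_index(drop=True)
    return SyntheticCohort(
        counts=matrix,
        histories=histories if len(histories) else _empty_events(),
        future_events=future if len(future) else _empty_events(),
        latents=latents_frame.drop(columns="patient_id").to_numpy(dtype=np.int8),
        record_counts=patients["n_records"].to_numpy(),
        disease_ids=disease_ids.astype(object).to_numpy(),
        config=config,
    )
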