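"""End-to-end experiment orchestration.

``run_experiment`` executes the full study once per representation on a
shared cohort, shared splits, and a shared classifier seed, so that the
comparison isolates the representation itself:

    simulate -> filter/scale (fit on feature-learning patients only)
             -> fit each representation on the feature-learning set
             -> transform classifier-train and test patients
             -> one-vs-all random forests per disease
             -> mask prior diagnoses, evaluate by disease and by patient
             -> side-by-side comparison table.

A single global seed derives one independent sub-seed per stage through a
fixed splitting scheme, so stages cannot couple through a shared random
stream and every output is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .autoencoder import StackedDenoisingAutoencoder
from .baselines import BaselineSpec, fit_baseline
from .classify import fit_one_vs_all, mask_prior_diagnoses, predict_probabilities
from .cohort import GeneratorConfig, SyntheticCohort, generate_cohort, split_cohort, write_cohort
from .labels import build_label_matrix, restrict_diseases, select_diseases
from .matrix import PatientMatrix
from .metrics import EvaluationReport, evaluate
from .preprocessing import filter_descriptors, scale_minmax

_STAGES = ("cohort", "split", "representations", "classifier")


def _stage_seeds(global_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _rep_seed(base: int, name: str) -> int:
    digest = hashlib.sha256(name.encode()).digest()
    return int(
        np.random.SeedSequence([base, int.from_bytes(digest[:4], "little")])
        .generate_state(1)[0]
        % (2**31)
    )


def default_representations() -> list[dict[str, Any]]:
    """The study's representation roster, sized for a desk-scale cohort.

    The shallow baselines' component counts are scaled to a
    few-hundred-descriptor cohort (their conventional defaults of
    100/100/500/200 assume tens of thousands of descriptors); likewise the
    SDA keeps three sigmoid layers but at 400 units with 30% masking noise
    and 100 epochs, settings selected on validation cohorts at this scale.
    """
    return [
        {"name": "rawfeat", "method": "rawfeat"},
        {"name": "pca", "method": "pca", "n_components": 50},
        {"name": "ica", "method": "ica", "n_components": 50},
        {"name": "kmeans", "method": "kmeans", "n_components": 100},
        {"name": "gmm", "method": "gmm", "n_components": 10,
         "extras": {"max_iter": 30}},
        {"name": "sda", "method": "sda", "n_layers": 3, "hidden_units": 400,
         "corruption": 0.3, "learning_rate": 0.1, "batch_size": 32,
         "n_epochs": 100},
    ]


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end experiment."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    representations: list[dict[str, Any]] = field(default_factory=default_representations)
    n_classifier_train: int = 400
    n_validation: int = 100
    n_test: int | None = 300
    min_records_featlearn: int = 5
    min_records_test: int = 10
    min_positive_train: int = 10
    n_trees: int = 100
    threshold: float = 0.6
    ks: tuple[int, ...] = (1, 3, 5)
    binary_counts: bool = False
    global_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        names = [r["name"] for r in self.representations]
        if len(set(names)) != len(names):
            raise ValueError("representation names must be unique")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["ks"] = list(self.ks)
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        if "ks" in data:
            data["ks"] = tuple(data["ks"])
        return cls(**data)


def _fit_representation(spec: dict[str, Any], X_train, seed: int):
    spec = dict(spec)
    spec.pop("name")
    method = spec.pop("method")
    if method == "sda":
        model = StackedDenoisingAutoencoder(random_state=seed, **spec)
        return model.fit(X_train)
    extras = spec.pop("extras", {})
    bspec = BaselineSpec(method=method, seed=seed, extras=extras, **spec)
    return fit_baseline(bspec, X_train)


@dataclass
class ExperimentResult:
    reports: dict[str, EvaluationReport]
    comparison: pd.DataFrame
    manifest: dict[str, Any]
    cohort: SyntheticCohort
    splits: Any


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def run_experiment(
    config: RunConfig, output_dir: str | Path | None = None
) -> ExperimentResult:
    """Run the full pipeline once per representation on identical splits.

    With ``output_dir`` set, artifacts (cohort files, reports, comparison
    table, manifest) are written there; per-representation reports found on
    disk with a matching configuration hash are reused instead of recomputed,
    making interrupted runs resumable.
    """
    seeds = _stage_seeds(config.global_seed)
    out = Path(output_dir) if output_dir is not None else None
    run_hash = _config_hash(config)

    gen_cfg = dataclasses.replace(config.generator, seed=seeds["cohort"])
    cohort = generate_cohort(gen_cfg)
    if out is not None:
        write_cohort(cohort, out / "cohort")
    splits = split_cohort(
        cohort,
        min_records_featlearn=config.min_records_featlearn,
        min_records_test=config.min_records_test,
        n_classifier_train=config.n_classifier_train,
        n_validation=config.n_validation,
        n_test=config.n_test,
        seed=seeds["split"],
    )

    matrix = cohort.counts
    if config.binary_counts:
        binary = matrix.values.copy()
        binary.data = (binary.data > 0).astype(float)
        matrix = PatientMatrix(binary, matrix.patient_ids, matrix.vocabulary, matrix.kinds)

    # raw representation: filter + scale, statistics frozen on the
    # feature-learning training patients
    feat_matrix = matrix.select_rows(splits.feature_train)
    feat_filtered, removed, fitted_filter = filter_descriptors(feat_matrix)
    feat_scaled, stats = scale_minmax(feat_filtered)

    def _prepare(rows: np.ndarray):
        sub = matrix.select_rows(rows)
        filtered, _, _ = filter_descriptors(sub, filter_=fitted_filter)
        scaled, _ = scale_minmax(filtered, stats=stats)
        return scaled

    clf_scaled = _prepare(splits.classifier_train)
    test_scaled = _prepare(splits.test)

    # labels: train labels at the widest window select the disease vocabulary
    windows = cohort.config.window_days
    max_window = max(windows)

    def _labels_for(rows: np.ndarray, window: int, diseases=None):
        ids = cohort.patient_ids[rows]
        keep = cohort.future_events["patient_id"].isin(set(ids))
        hist_keep = cohort.histories["patient_id"].isin(set(ids))
        lm = build_label_matrix(
            cohort.future_events[keep],
            cohort.histories[hist_keep],
            window,
            cohort.disease_ids,
            ids,
        )
        return lm if diseases is None else restrict_diseases(lm, diseases)

    train_labels_full = _labels_for(splits.classifier_train, max_window)
    diseases = select_diseases(train_labels_full, config.min_positive_train)
    train_labels = restrict_diseases(train_labels_full, diseases)
    test_labels = [
        _labels_for(splits.test, w, diseases) for w in windows
    ]
    widest_test = test_labels[-1]

    reports: dict[str, EvaluationReport] = {}
    for spec in config.representations:
        name = spec["name"]
        report_path = None
        if out is not None:
            report_path = out / "reports" / f"{name}.json"
            marker = out / "reports" / f"{name}.hash"
            if report_path.exists() and marker.exists() and marker.read_text() == run_hash:
                reports[name] = EvaluationReport.from_json(report_path)
                continue
        rep_seed = _rep_seed(seeds["representations"], name)
        model = _fit_representation(spec, feat_scaled.values, rep_seed)
        clf_features = model.transform(clf_scaled.values)
        test_features = model.transform(test_scaled.values)
        ensemble = fit_one_vs_all(
            clf_features, train_labels, n_trees=config.n_trees,
            seed=seeds["classifier"],
        )
        preds = predict_probabilities(
            ensemble, test_features, widest_test.patient_ids
        )
        preds = mask_prior_diagnoses(preds, widest_test.prior)
        report = evaluate(
            preds, test_labels, threshold=config.threshold, ks=config.ks
        )
        reports[name] = report
        if report_path is not None:
            report_path.parent.mkdir(parents=True, exist_ok=True)
            report.to_json(report_path)
            preds.to_tsv(out / "reports" / f"{name}_scores.tsv")
            marker.write_text(run_hash)

    comparison = compare_representations(reports)
    manifest = {
        "config": config.to_dict(),
        "config_hash": run_hash,
        "stage_seeds": seeds,
        "n_patients": cohort.counts.n_patients,
        "n_descriptors_removed": len(removed),
        "n_diseases_evaluated": len(diseases),
        "split_sizes": {
            "feature_train": int(len(splits.feature_train)),
            "classifier_train": int(len(splits.classifier_train)),
            "validation": int(len(splits.validation)),
            "test": int(len(splits.test)),
        },
    }
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        comparison.to_csv(out / "comparison.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(reports, comparison, manifest, cohort, splits)


def compare_representations(
    reports: Mapping[str, EvaluationReport],
) -> pd.DataFrame:
    """Side-by-side representation x metric table with best-per-metric flags.

    Rows are representations; columns are the macro disease metrics plus the
    widest-window tagging metrics.  The ``best`` row names the representation
    with the highest value per column (blank on ties).
    """
    if not reports:
        raise ValueError("no reports to compare")
    vocabularies = [tuple(r.by_disease["disease_id"]) for r in reports.values()]
    if len(set(vocabularies)) != 1:
        raise ValueError("reports do not share a disease vocabulary")
    rows = {}
    for name, report in reports.items():
        row = dict(report.macro)
        row.pop("n_diseases", None)
        widest = report.by_patient.sort_values("window_days").iloc[-1]
        for col in report.by_patient.columns:
            if col.startswith(("prec_at_", "r_precision")):
                row[col] = widest[col]
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "representation"
    best = {}
    for col in table.columns:
        top = table[col].max()
        winners = table.index[table[col] == top]
        best[col] = winners[0] if len(winners) == 1 else ""
    table.attrs["best"] = best
    return table


def paired_sign_test(a: Sequence[float], b: Sequence[float]) -> float:
    """One-sided sign test that paired values in ``a`` exceed those in ``b``.

    Ties are discarded; the p-value is the binomial tail
    P[Binom(n_informative, 1/2) >= wins].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    informative = a != b
    n = int(informative.sum())
    if n == 0:
        return 1.0
    wins = int(np.sum(a[informative] > b[informative]))
    return float(binomtest(wins, n, 0.5, alternative="greater").pvalue)


def compare_across_seeds(
    runs: Sequence[Mapping[str, EvaluationReport]],
    metric: str = "auc",
    reference: str = "rawfeat",
) -> pd.DataFrame:
    """Aggregate one macro metric across seeds and sign-test against a
    reference representation."""
    if not runs:
        raise ValueError("no runs supplied")
    names = list(runs[0].keys())
    values = pd.DataFrame(
        {name: [run[name].macro[metric] for run in runs] for name in names}
    )
    out = pd.DataFrame(
        {
            "mean": values.mean(),
            "std": values.std(ddof=1) if len(runs) > 1 else np.nan,
            "wins_vs_reference": [
                int(np.sum(values[n].to_numpy() > values[reference].to_numpy()))
                for n in names
            ],
            "sign_test_p": [
                paired_sign_test(values[n], values[reference]) for n in names
            ],
        }
    )
    out.index.name = "representation"
    return out
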