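import numpy as np
import pytest
from hypothesis import given, strategies as st

import patientrep as pr
from oracles import (
    auc_by_pair_enumeration,
    prec_at_k_by_enumeration,
    r_precision_by_enumeration,
    upper_bound_by_enumeration,
    random_tagging_instance,
)


def _wrap(scores, prior, labels, window=180):
    n, d = scores.shape
    pids = [f"p{i}" for i in range(n)]
    dids = [f"d{j}" for j in range(d)]
    preds = pr.PredictionMatrix(scores, prior.copy(), pids, dids)
    lm = pr.DiseaseLabelMatrix(labels, prior, window, pids, dids)
    return preds, lm


class TestRocAuc:
    def test_perfect_separation(self):
        assert pr.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert pr.roc_auc([0.4, 0.4, 0.4], [1, 0, 1]) == 0.5

    def test_worked_four_pair_example(self):
        # pairs: (.9>.8)=1, (.9>.1)=1, (.8 vs .8)=.5, (.8>.1)=1 -> 3.5/4
        assert pr.roc_auc([0.9, 0.8, 0.8, 0.1], [1, 0, 1, 0]) == pytest.approx(0.875)

    def test_single_class_error_names_the_disease(self):
        with pytest.raises(ValueError, match="gout"):
            pr.roc_auc([0.1, 0.2], [1, 1], name="gout")

    @given(st.integers(0, 2**32 - 1))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.random(12) < 0.4
        if labels.all() or not labels.any():
            return
        scores = np.round(rng.random(12), 1)  # coarse grid forces ties
        assert pr.roc_auc(scores, labels) == pytest.approx(
            auc_by_pair_enumeration(scores, labels), abs=1e-12
        )

    @given(st.integers(0, 2**32 - 1))
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.random(15) < 0.5
        if labels.all() or not labels.any():
            return
        scores = rng.random(15)
        assert pr.roc_auc(np.exp(3 * scores), labels) == pytest.approx(
            pr.roc_auc(scores, labels)
        )

    def test_score_negation_complements_auc_without_ties(self, rng):
        labels = np.array([1, 0, 1, 0, 0, 1], dtype=bool)
        scores = rng.permutation(np.linspace(0.1, 0.9, 6))
        assert pr.roc_auc(scores, labels) + pr.roc_auc(-scores, labels) == pytest.approx(1.0)


class TestThresholdMetrics:
    def test_worked_example(self):
        m = pr.threshold_metrics([0.7, 0.5], [1, 0], threshold=0.6)
        assert m.accuracy == 1.0 and m.f_score == 1.0

    def test_no_predicted_positive_gives_zero_f(self):
        m = pr.threshold_metrics([0.1, 0.2], [1, 0], threshold=0.6)
        assert m.f_score == 0.0 and m.precision == 0.0

    def test_exact_threshold_counts_as_positive(self):
        m = pr.threshold_metrics([0.6], [1], threshold=0.6)
        assert m.recall == 1.0
        strict = pr.threshold_metrics([0.6], [1], threshold=0.6, inclusive=False)
        assert strict.recall == 0.0

    def test_confusion_matrix_arithmetic(self):
        scores = [0.9, 0.7, 0.3, 0.8, 0.1]
        labels = [1, 0, 1, 1, 0]
        m = pr.threshold_metrics(scores, labels, threshold=0.6)
        # predictions: 1,1,0,1,0 -> TP=2 FP=1 FN=1 TN=1
        assert m.accuracy == pytest.approx(3 / 5)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f_score == pytest.approx(2 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pr.threshold_metrics([], [])


class TestTaggingMetrics:
    def test_perfect_top_three(self):
        scores = np.array([[0.9, 0.8, 0.7, 0.1]])
        labels = np.array([[True, True, True, False]])
        preds, lm = _wrap(scores, np.zeros_like(labels), labels)
        assert pr.precision_at_k(preds, lm, 3) == 1.0

    def test_two_of_three_correct(self):
        scores = np.array([[0.9, 0.8, 0.7, 0.1]])
        labels = np.array([[True, False, True, False]])
        preds, lm = _wrap(scores, np.zeros_like(labels), labels)
        assert pr.precision_at_k(preds, lm, 3) == pytest.approx(2 / 3)

    def test_denominator_stays_k_with_few_candidates(self):
        scores = np.array([[0.9, 0.1, 0.1, 0.1]])  # one candidate above 0.6
        labels = np.array([[True, True, False, False]])
        preds, lm = _wrap(scores, np.zeros_like(labels), labels)
        assert pr.precision_at_k(preds, lm, 5) == pytest.approx(1 / 5)

    def test_invalid_k_rejected(self):
        scores = np.array([[0.9]])
        labels = np.array([[True]])
        preds, lm = _wrap(scores, np.zeros_like(labels), labels)
        with pytest.raises(ValueError):
            pr.precision_at_k(preds, lm, 0)
        with pytest.raises(ValueError):
            pr.upper_bound_precision_at_k(lm, 0)

    def test_r_precision_single_and_half(self):
        scores = np.array([[0.9, 0.2, 0.1], [0.9, 0.8, 0.1]])
        labels = np.array([[True, False, False], [True, False, True]])
        preds, lm = _wrap(scores, np.zeros_like(labels), labels)
        # p0: R=1, top-1 true -> 1.0 ; p1: R=2, top-2 has 1 true -> 0.5
        assert pr.r_precision(preds, lm) == pytest.approx(0.75)

    def test_r_precision_equals_prec_at_k_when_all_r_equal_k(self, rng):
        scores, prior, _ = random_tagging_instance(rng)
        labels = np.zeros_like(prior)
        for i in range(labels.shape[0]):  # exactly 2 true diseases each
            free = np.flatnonzero(~prior[i])
            labels[i, rng.choice(free, 2, replace=False)] = True
        preds, lm = _wrap(scores, prior, labels)
        assert pr.r_precision(preds, lm, keep_below_threshold=False) == pytest.approx(
            pr.precision_at_k(preds, lm, 2)
        )

    def test_upper_bound_values(self):
        labels = np.array([[True, False, False], [True, True, False]])
        lm = pr.DiseaseLabelMatrix(labels, np.zeros_like(labels), 30,
                                   ["p1", "p2"], ["a", "b", "c"])
        assert pr.upper_bound_precision_at_k(lm, 1) == 1.0
        assert pr.upper_bound_precision_at_k(lm, 5) == pytest.approx(
            ((1 / 5) + (2 / 5)) / 2
        )

    def test_upper_bound_dominates_every_tagger(self, rng):
        scores, prior, labels = random_tagging_instance(rng)
        _, lm = _wrap(scores, prior, labels)
        for k in (1, 3, 5):
            ub = pr.upper_bound_precision_at_k(lm, k)
            for _ in range(100):
                random_scores = rng.random(scores.shape)
                preds, _ = _wrap(random_scores, prior, labels)
                assert pr.precision_at_k(preds, lm, k, threshold=0.0) <= ub + 1e-12

    def test_fully_masked_patient_is_excluded(self):
        scores = np.array([[0.9, 0.9], [0.9, 0.2]])
        prior = np.array([[True, True], [False, False]])
        labels = np.array([[False, False], [True, False]])
        preds, lm = _wrap(scores, prior, labels)
        assert pr.precision_at_k(preds, lm, 1) == 1.0  # only p2 graded

    @given(st.integers(0, 2**32 - 1))
    def test_tagging_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        scores, prior, labels = random_tagging_instance(rng)
        preds, lm = _wrap(scores, prior, labels)
        for k in (1, 3, 5):
            assert pr.precision_at_k(preds, lm, k) == pytest.approx(
                prec_at_k_by_enumeration(scores, prior, labels, k), abs=1e-12
            )
            assert pr.upper_bound_precision_at_k(lm, k) == pytest.approx(
                upper_bound_by_enumeration(labels, k), abs=1e-12
            )
        assert pr.r_precision(preds, lm) == pytest.approx(
            r_precision_by_enumeration(scores, prior, labels), abs=1e-12
        )


class TestEvaluate:
    def _hand_case(self):
        # 5 patients, 2 diseases, windows 30/180
        scores = np.array(
            [[0.9, 0.1], [0.7, 0.8], [0.2, 0.3], [0.65, 0.1], [0.1, 0.9]]
        )
        prior = np.zeros((5, 2), dtype=bool)
        prior[4, 0] = True  # p5 already had disease a
        labels_180 = np.array(
            [[1, 0], [1, 1], [0, 0], [0, 0], [0, 1]], dtype=bool
        )
        labels_30 = np.array(
            [[1, 0], [0, 0], [0, 0], [0, 0], [0, 1]], dtype=bool
        )
        pids = [f"p{i}" for i in range(5)]
        dids = ["a", "b"]
        preds = pr.PredictionMatrix(scores, prior, pids, dids)
        lm30 = pr.DiseaseLabelMatrix(labels_30, prior, 30, pids, dids)
        lm180 = pr.DiseaseLabelMatrix(labels_180, prior, 180, pids, dids)
        return preds, [lm30, lm180]

    def test_hand_worked_report(self):
        preds, windows = self._hand_case()
        report = pr.evaluate(preds, windows)
        by_d = report.by_disease.set_index("disease_id")
        # disease a: population p1..p4 (p5 masked), scores (.9,.7,.2,.65),
        # labels (1,1,0,0) -> AUC 1.0; preds at 0.6: (1,1,0,1) -> acc 3/4
        assert by_d.loc["a", "auc"] == 1.0
        assert by_d.loc["a", "n_eval_patients"] == 4
        assert by_d.loc["a", "accuracy"] == pytest.approx(0.75)
        # disease b: all 5 patients, scores (.1,.8,.3,.1,.9), labels (0,1,0,0,1)
        assert by_d.loc["b", "auc"] == 1.0
        assert by_d.loc["b", "accuracy"] == 1.0
        assert report.macro["auc"] == pytest.approx(1.0)
        assert report.macro["accuracy"] == pytest.approx(
            by_d["accuracy"].mean()
        )
        by_p = report.by_patient.set_index("window_days")
        assert by_p.loc[30, "n_patients"] == 2
        assert by_p.loc[180, "n_patients"] == 3  # p1, p2, p5 have in-window truth
        assert by_p.loc[180, "uppbnd_prec_at_1"] == 1.0
        # window 30: p1 tags (a:.9) true -> 1; p5 tags (b:.9) true -> 1
        assert by_p.loc[30, "prec_at_1"] == 1.0

    def test_macro_equals_mean_of_per_disease_column(self, rng):
        scores, prior, labels = random_tagging_instance(rng, 30, 6)
        preds, lm = _wrap(scores, prior, labels)
        report = pr.evaluate(preds, lm)
        assert report.macro["auc"] == pytest.approx(report.by_disease["auc"].mean())

    def test_single_class_disease_reported_in_warnings(self):
        scores = np.array([[0.5, 0.5], [0.6, 0.4]])
        labels = np.array([[True, False], [False, False]])
        preds, lm = _wrap(scores, np.zeros_like(labels), labels)
        report = pr.evaluate(preds, lm)
        assert len(report.warnings) == 1 and "d1" in report.warnings[0]
        assert list(report.by_disease["disease_id"]) == ["d0"]

    def test_micro_average_pools_cells(self, rng):
        scores, prior, labels = random_tagging_instance(rng, 30, 6)
        preds, lm = _wrap(scores, prior, labels)
        micro = pr.evaluate(preds, lm, average="micro")
        flat = ~prior.ravel()
        assert micro.macro["auc"] == pytest.approx(
            pr.roc_auc(scores.ravel()[flat], labels.ravel()[flat])
        )

    def test_report_json_round_trip(self, rng, tmp_path):
        scores, prior, labels = random_tagging_instance(rng, 20, 5)
        preds, lm = _wrap(scores, prior, labels)
        report = pr.evaluate(preds, lm)
        report.to_json(tmp_path / "r.json")
        back = pr.EvaluationReport.from_json(tmp_path / "r.json")
        assert back.macro == report.macro
        assert back.by_disease.equals(report.by_disease)
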