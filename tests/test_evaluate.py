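"""Confusion matrix and metric-suite contracts."""

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, precision_recall_fscore_support)

from hctgnet import (HctgNet, ModelConfig, aggregate, class_metrics,
                     confusion_matrix, evaluate_model, report_from_confusion)
from hctgnet.balance import SmoteConfig, smote_oversample
from hctgnet.wfdb_io import CLASSES


def _random_labels(rng, n, p=None):
    return rng.choice(list(CLASSES), size=n, p=p).astype("U1")


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        y = _random_labels(rng, 60)
        cm = confusion_matrix(y, y)
        assert np.all(cm == np.diag(np.diag(cm)))
        assert cm.sum() == 60

    def test_direct_count_example(self):
        cm = confusion_matrix(["N", "N", "S"], ["N", "S", "S"])
        expected = np.zeros((5, 5), dtype=int)
        expected[0, 0] = 1   # N -> N
        expected[0, 1] = 1   # N -> S
        expected[1, 1] = 1   # S -> S
        np.testing.assert_array_equal(cm, expected)

    def test_row_sums_equal_true_class_counts(self, rng):
        y_true = _random_labels(rng, 200)
        y_pred = _random_labels(rng, 200)
        cm = confusion_matrix(y_true, y_pred)
        for k, cls in enumerate(CLASSES):
            assert cm[k].sum() == np.sum(y_true == cls)

    def test_unknown_label_named(self):
        with pytest.raises(ValueError, match="'X'"):
            confusion_matrix(["N", "X"], ["N", "N"])


class TestClassMetrics:
    def test_direct_arithmetic(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 9    # TP for N
        cm[1, 0] = 1    # FP for N
        cm[0, 1] = 1    # FN for N
        p, r, f1, und = class_metrics(cm, 0)
        assert (p, r, f1) == (0.9, 0.9, 0.9)
        assert not und

    def test_equal_precision_recall_gives_same_f1(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[2, 2] = 3
        cm[2, 0] = 1
        cm[0, 2] = 1
        p, r, f1, _ = class_metrics(cm, 2)
        assert p == r == 0.75
        assert abs(f1 - 0.75) < 1e-12

    def test_absent_class_flagged_as_undefined_zero(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 10
        p, r, f1, und = class_metrics(cm, 3)
        assert (p, r, f1) == (0.0, 0.0, 0.0)
        assert und


class TestAggregate:
    def test_identical_class_metrics_pass_through(self):
        triples = [(0.8, 0.7, 0.75)] * 5
        macro, weighted, _acc = aggregate(triples, [3, 7, 1, 4, 5], 10)
        assert macro == weighted == {"precision": 0.8, "recall": 0.7,
                                     "f1": 0.75}

    def test_weighted_mean_arithmetic(self):
        triples = [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5)] + [(0.0, 0.0, 0.0)] * 3
        macro, weighted, _ = aggregate(triples, [90, 10, 0, 0, 0], 80)
        assert abs(weighted["f1"] - 0.95) < 1e-12
        assert abs(macro["f1"] - 0.3) < 1e-12

    def test_equal_supports_make_macro_equal_weighted(self):
        triples = [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5)] + [(0.0, 0.0, 0.0)] * 3
        macro, weighted, _ = aggregate(triples[:2] + triples[2:],
                                       [10, 10, 0, 0, 0], 15)
        # with supports only on the first two classes, weighted uses them
        assert abs(weighted["f1"] - 0.75) < 1e-12


class TestReport:
    def test_agrees_with_sklearn_on_random_predictions(self, rng):
        """Cross-library oracle, 100 random prediction vectors at 1e-9."""
        for _ in range(100):
            n = int(rng.integers(20, 120))
            y_true = _random_labels(rng, n)
            y_pred = _random_labels(rng, n)
            rep = report_from_confusion(confusion_matrix(y_true, y_pred))
            p, r, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=list(CLASSES), zero_division=0)
            for k, cls in enumerate(CLASSES):
                assert abs(rep.per_class[cls]["precision"] - p[k]) < 1e-9
                assert abs(rep.per_class[cls]["recall"] - r[k]) < 1e-9
                assert abs(rep.per_class[cls]["f1"] - f1[k]) < 1e-9
            mp, mr, mf1, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=list(CLASSES), average="macro",
                zero_division=0)
            assert abs(rep.macro_avg["f1"] - mf1) < 1e-9
            wp, wr, wf1, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=list(CLASSES), average="weighted",
                zero_division=0)
            assert abs(rep.weighted_avg["f1"] - wf1) < 1e-9
            assert abs(rep.accuracy - accuracy_score(y_true, y_pred)) < 1e-9
            # single-label multiclass identity: weighted recall == accuracy
            assert abs(rep.weighted_avg["recall"] - rep.accuracy) < 1e-9

    def test_accuracy_equals_trace_over_total(self, rng):
        y_true = _random_labels(rng, 300)
        y_pred = _random_labels(rng, 300)
        cm = confusion_matrix(y_true, y_pred)
        rep = report_from_confusion(cm)
        assert rep.accuracy == np.trace(cm) / cm.sum()

    def test_macro_bounded_by_per_class_extremes(self, rng):
        y_true = _random_labels(rng, 250)
        y_pred = _random_labels(rng, 250)
        rep = report_from_confusion(confusion_matrix(y_true, y_pred))
        f1s = [rep.per_class[c]["f1"] for c in CLASSES]
        assert min(f1s) <= rep.macro_avg["f1"] <= max(f1s)

    def test_accuracy_misleading_under_imbalance(self, rng):
        """High accuracy can hide minority-class failure; macro F1 exposes it."""
        y_true = _random_labels(rng, 1000, p=[0.96, 0.01, 0.01, 0.01, 0.01])
        y_pred = np.full(1000, "N", dtype="U1")  # majority-only predictor
        rep = report_from_confusion(confusion_matrix(y_true, y_pred))
        assert rep.accuracy > 0.9
        assert rep.macro_avg["f1"] < 0.3

    def test_table_rendering_contains_all_rows(self, rng):
        y = _random_labels(rng, 50)
        rep = report_from_confusion(confusion_matrix(y, y))
        table = rep.to_table()
        for token in list(CLASSES) + ["Macro Average", "Weighted Average",
                                      "Accuracy"]:
            assert token in table


class TestEvaluateModel:
    def test_perfect_classifier_hook(self, small_dataset):
        rep = evaluate_model(None, small_dataset,
                             predict_fn=lambda beats: small_dataset.labels)
        assert rep.accuracy == 1.0
        assert all(rep.per_class[c]["f1"] == 1.0 for c in CLASSES)

    def test_constant_predictor_on_balanced_classes(self, small_dataset):
        rep = evaluate_model(
            None, small_dataset,
            predict_fn=lambda beats: np.full(len(beats), "N", dtype="U1"))
        assert abs(rep.accuracy - 0.2) < 1e-12

    def test_balanced_test_set_refused(self, small_dataset):
        balanced = smote_oversample(small_dataset, SmoteConfig(seed=0))
        with pytest.raises(ValueError, match="balanced"):
            evaluate_model(None, balanced, predict_fn=lambda b: None)

    def test_model_inference_path(self, small_dataset):
        net = HctgNet(ModelConfig(variant="cnn_only"), seed=0).eval()
        rep = evaluate_model(net, small_dataset)
        assert rep.n_samples == len(small_dataset)
        assert rep.confusion.sum() == len(small_dataset)

    def test_report_json_roundtrip(self, tmp_path, small_dataset):
        import json

        rep = evaluate_model(None, small_dataset,
                             predict_fn=lambda b: small_dataset.labels)
        rep.to_json(tmp_path / "rep.json")
        payload = json.loads((tmp_path / "rep.json").read_text())
        assert payload["accuracy"] == 1.0
        assert payload["class_order"] == list(CLASSES)
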