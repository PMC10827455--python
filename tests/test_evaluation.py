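"""Metrics against brute-force oracles: confusion, F1, ROC-AUC."""

import numpy as np
import pytest

import histolearn as H
from histolearn.datamodel import CLASSES


# --- brute-force oracles ----------------------------------------------------

def brute_confusion(true, pred):
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(true, pred):
        cm[CLASSES.index(t), CLASSES.index(p)] += 1
    return cm


def brute_metrics(true, pred):
    acc = sum(t == p for t, p in zip(true, pred)) / len(true)
    f1 = {}
    for cls in CLASSES:
        tp = sum(1 for t, p in zip(true, pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(true, pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(true, pred) if t == cls and p != cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1[cls] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, f1


def brute_auc(scores, truth):
    """Concordant-pair fraction with 0.5 credit for ties (n <= 200)."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                concordant += 1
            elif p == q:
                concordant += 0.5
    return concordant / total


def _random_labels(rng, n):
    return [CLASSES[i] for i in rng.integers(0, 2, n)]


# --- confusion matrix -------------------------------------------------------

class TestConfusion:
    def test_459_samples_10_misclassified(self):
        true = ["benign"] * 150 + ["malignant"] * 309
        pred = (["benign"] * 144 + ["malignant"] * 6
                + ["benign"] * 4 + ["malignant"] * 305)
        cm = H.confusion_matrix(true, pred)
        assert cm.sum() == 459
        assert cm.sum() - np.trace(cm) == 10
        assert H.classification_metrics(cm)["accuracy"] \
            == pytest.approx(449 / 459)

    def test_perfect_predictions_are_diagonal(self, rng):
        labels = _random_labels(rng, 50)
        cm = H.confusion_matrix(labels, labels)
        assert np.trace(cm) == 50
        assert H.classification_metrics(cm)["accuracy"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        true, pred = _random_labels(rng, 97), _random_labels(rng, 97)
        np.testing.assert_array_equal(H.confusion_matrix(true, pred),
                                      brute_confusion(true, pred))

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            H.confusion_matrix(["benign"], ["benign", "malignant"])


class TestClassificationMetrics:
    def test_all_one_for_diagonal_matrix(self):
        m = H.classification_metrics(np.array([[10, 0], [0, 20]]))
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0
        assert all(v == 1.0 for v in m["f1_per_class"].values())

    def test_degenerate_column_reports_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="histolearn"):
            m = H.classification_metrics(np.array([[0, 5], [0, 5]]))
        assert m["recall_per_class"]["benign"] == 0.0
        assert m["f1_per_class"]["benign"] == 0.0
        assert "undefined" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_from_raw_pairs(self, seed):
        rng = np.random.default_rng(seed)
        true, pred = _random_labels(rng, 120), _random_labels(rng, 120)
        m = H.classification_metrics(H.confusion_matrix(true, pred))
        acc, f1 = brute_metrics(true, pred)
        assert m["accuracy"] == pytest.approx(acc)
        for cls in CLASSES:
            assert m["f1_per_class"][cls] == pytest.approx(f1[cls])

    def test_accuracy_equals_trace_over_sum(self, rng):
        cm = rng.integers(0, 30, (2, 2))
        m = H.classification_metrics(cm)
        assert m["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        truth = ["benign"] * 5 + ["malignant"] * 5
        p_mal = np.array([0.1, 0.2, 0.15, 0.05, 0.3, 0.9, 0.8, 0.95, 0.85, 0.7])
        scores = np.column_stack([1 - p_mal, p_mal])
        _, auc = H.roc_auc(scores, truth)
        assert auc["malignant"] == pytest.approx(1.0)
        assert auc["benign"] == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        truth = _random_labels(rng, n)
        p = rng.random(n)
        _, auc = H.roc_auc(np.column_stack([1 - p, p]), truth)
        assert auc["malignant"] == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        truth_idx = rng.integers(0, 2, n)
        truth = [CLASSES[i] for i in truth_idx]
        # quantized scores force ties so the midpoint convention is exercised
        p = np.round(rng.random(n), 1)
        _, auc = H.roc_auc(np.column_stack([1 - p, p]), truth)
        assert auc["malignant"] == pytest.approx(brute_auc(p, truth_idx))

    def test_invariant_under_monotone_transform(self, rng):
        n = 100
        truth = _random_labels(rng, n)
        p = rng.random(n)
        _, a1 = H.roc_auc(np.column_stack([1 - p, p]), truth)
        q = p ** 3
        _, a2 = H.roc_auc(np.column_stack([1 - q, q]), truth)
        assert a1["malignant"] == pytest.approx(a2["malignant"])

    def test_flipping_scores_complements_auc(self, rng):
        n = 80
        truth_idx = rng.integers(0, 2, n)
        truth = [CLASSES[i] for i in truth_idx]
        p = rng.random(n)
        _, auc = H.roc_auc(np.column_stack([1 - p, p]), truth)
        assert auc["malignant"] + brute_auc(1 - p, truth_idx) \
            == pytest.approx(1.0)

    def test_roc_endpoints(self, rng):
        truth = _random_labels(rng, 40)
        p = rng.random(40)
        points, _ = H.roc_auc(np.column_stack([1 - p, p]), truth)
        for cls in CLASSES:
            np.testing.assert_allclose(points[cls][0], [0, 0])
            np.testing.assert_allclose(points[cls][-1], [1, 1])

    def test_single_class_truth_yields_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="histolearn"):
            _, auc = H.roc_auc(np.array([[0.4, 0.6], [0.3, 0.7]]),
                               ["malignant", "malignant"])
        assert np.isnan(auc["benign"])
        assert "undefined" in caplog.text

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            H.roc_auc(np.array([[1.2, -0.2]]), ["benign"])


class TestMagnificationReport:
    def _report(self, acc=0.9):
        n_correct = int(round(acc * 100))
        true = ["benign"] * 50 + ["malignant"] * 50
        p_mal = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        flip = 100 - n_correct
        p_mal[:flip] = 0.9   # make `flip` benign samples wrong
        return H.build_report(true, np.column_stack([1 - p_mal, p_mal]))

    def test_four_tiers_four_rows(self):
        reports = {m: self._report() for m in H.MAGNIFICATIONS}
        assert len(H.magnification_report(reports)) == 4

    def test_missing_tier_row_omitted_with_warning(self, caplog):
        reports = {m: self._report() for m in (40, 100, 400)}
        with caplog.at_level("WARNING", logger="histolearn"):
            table = H.magnification_report(reports)
        assert len(table) == 3
        assert 200 not in list(table["magnification"])
        assert "omitted" in caplog.text

    def test_rows_project_report_fields(self):
        reports = {m: self._report(acc=0.85) for m in H.MAGNIFICATIONS}
        table = H.magnification_report(reports)
        for _, row in table.iterrows():
            rep = reports[row["magnification"]]
            assert row["accuracy"] == rep.accuracy
            assert row["macro_f1"] == rep.macro_f1
            assert row["auc_malignant"] == rep.auc_per_class["malignant"]

    def test_identical_inputs_zero_between_tier_variance(self):
        reports = {m: self._report() for m in H.MAGNIFICATIONS}
        table = H.magnification_report(reports)
        assert table["accuracy"].nunique() == 1


def test_report_serializes_to_json(tmp_path, rng):
    truth = _random_labels(rng, 30)
    p = rng.random(30)
    report = H.build_report(truth, np.column_stack([1 - p, p]))
    path = tmp_path / "report.json"
    report.to_json(str(path))
    import json
    loaded = json.loads(path.read_text())
    assert loaded["accuracy"] == pytest.approx(report.accuracy)
    assert np.array(loaded["confusion"]).sum() == 30
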