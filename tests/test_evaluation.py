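import numpy as np
import pytest

from leaffusion.balancing import FeatureMatrix
from leaffusion.evaluation import (
    CLASSIFIER_NAMES,
    ClassifierSpec,
    build_classifier,
    confusion_matrix,
    confusion_metrics,
    kfold_evaluate,
    soft_vote,
    split_dataset,
    stratified_folds,
)


class TestSplitDataset:
    def test_70_15_15(self):
        data = FeatureMatrix(np.zeros((100, 2)), np.zeros(100, dtype=int), ["only"])
        train, val, test = split_dataset(data, (0.7, 0.15, 0.15), seed=0)
        assert (len(train.y), len(val.y), len(test.y)) == (70, 15, 15)

    def test_partition(self, blob_matrix):
        train, val, test = split_dataset(blob_matrix, seed=3)
        all_y = np.concatenate([train.y, val.y, test.y])
        assert len(all_y) == len(blob_matrix.y)
        assert len(train.y) + len(val.y) + len(test.y) == 60

    def test_stratified_per_class(self, blob_matrix):
        train, val, test = split_dataset(blob_matrix, seed=3)
        for sub, expect in [(train, 14), (val, 3), (test, 3)]:
            assert list(np.bincount(sub.y, minlength=3)) == [expect] * 3

    def test_deterministic(self, blob_matrix):
        a = split_dataset(blob_matrix, seed=9)
        b = split_dataset(blob_matrix, seed=9)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.X, mb.X)

    def test_bad_fractions_rejected(self, blob_matrix):
        with pytest.raises(ValueError):
            split_dataset(blob_matrix, (0.5, 0.2, 0.2), seed=0)

    def test_tiny_class_falls_back_to_train(self, caplog):
        X = np.vstack([np.zeros((10, 2)), np.ones((2, 2))])
        y = np.array([0] * 10 + [1] * 2)
        data = FeatureMatrix(X, y, ["big", "tiny"])
        with caplog.at_level("WARNING"):
            train, val, test = split_dataset(data, seed=0)
        assert np.sum(train.y == 1) == 2
        assert "tiny" in caplog.text


class TestBuildClassifier:
    def test_knn_default_neighbors(self):
        model = build_classifier(ClassifierSpec(name="KNN"))
        assert model.n_neighbors == 5

    def test_table_defaults(self):
        svm = build_classifier(ClassifierSpec(name="SVM"))
        assert (svm.C, svm.gamma, svm.kernel, svm.probability) == (10.0, 0.1, "rbf", True)
        rf = build_classifier(ClassifierSpec(name="RandomForest"))
        assert rf.n_estimators == 100
        lr = build_classifier(ClassifierSpec(name="LogisticRegression"))
        assert lr.max_iter == 1000
        gb = build_classifier(ClassifierSpec(name="GradientBoost"))
        assert (gb.n_estimators, gb.learning_rate, gb.max_depth) == (100, 0.1, 3)
        ab = build_classifier(ClassifierSpec(name="AdaBoost"))
        assert (ab.n_estimators, ab.learning_rate) == (50, 1.0)
        dt = build_classifier(ClassifierSpec(name="DecisionTree"))
        assert (dt.criterion, dt.max_depth, dt.min_samples_split) == ("gini", None, 2)

    def test_lr_separates_blobs(self, blob_matrix):
        model = build_classifier(ClassifierSpec(name="LogisticRegression"))
        model.fit(blob_matrix.X, blob_matrix.y)
        assert np.mean(model.predict(blob_matrix.X) == blob_matrix.y) == 1.0

    @pytest.mark.parametrize("name", [n for n in CLASSIFIER_NAMES if n != "SoftVote"])
    def test_deterministic_predictions(self, name, blob_matrix):
        preds = []
        for _ in range(2):
            m = build_classifier(ClassifierSpec(name=name, seed=42))
            m.fit(blob_matrix.X, blob_matrix.y)
            preds.append(m.predict(blob_matrix.X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_softvote_handle(self, blob_matrix):
        m = build_classifier(ClassifierSpec(name="SoftVote"))
        m.fit(blob_matrix.X, blob_matrix.y)
        proba = m.predict_proba(blob_matrix.X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.mean(m.predict(blob_matrix.X) == blob_matrix.y) == 1.0

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="RandomForest"):
            ClassifierSpec(name="Perceptron")


class TestSoftVote:
    def test_weighted_mean_argmax(self):
        a = np.array([[0.6, 0.4]])
        b = np.array([[0.2, 0.8]])
        assert soft_vote([a, b]).tolist() == [1]

    def test_unanimous(self):
        a = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert soft_vote([a, a, a]).tolist() == [0, 1]

    def test_tie_goes_to_lowest_index(self):
        a = np.array([[0.5, 0.5]])
        b = np.array([[0.5, 0.5]])
        assert soft_vote([a, b]).tolist() == [0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            soft_vote([np.ones((2, 2)) / 2, np.ones((3, 2)) / 2])

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([np.ones((2, 2)) / 2])

    def test_identical_members_match_single(self, blob_matrix):
        m = build_classifier(ClassifierSpec(name="RandomForest", seed=0))
        m.fit(blob_matrix.X, blob_matrix.y)
        p = m.predict_proba(blob_matrix.X)
        np.testing.assert_array_equal(soft_vote([p, p]), np.argmax(p, axis=1))


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        m = confusion_metrics(np.diag([5, 3, 2]))
        assert m["accuracy"] == 1.0
        np.testing.assert_array_equal(m["precision"], 1.0)
        np.testing.assert_array_equal(m["recall"], 1.0)
        np.testing.assert_array_equal(m["f1"], 1.0)

    def test_hand_arithmetic_2x2(self):
        m = confusion_metrics(np.array([[8, 2], [3, 7]]))
        assert m["precision"][0] == pytest.approx(8 / 11)
        assert m["recall"][0] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.75)

    def test_never_predicted_class_zero_precision(self):
        cm = np.array([[5, 0], [3, 0]])  # class 1 never predicted
        m = confusion_metrics(cm)
        assert m["precision"][1] == 0.0
        assert m["f1"][1] == 0.0

    def test_micro_recall_equals_accuracy_random(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 6))
            cm = rng.integers(0, 20, size=(k, k))
            m = confusion_metrics(cm)
            micro_recall = np.trace(cm) / cm.sum()
            assert m["accuracy"] == pytest.approx(micro_recall)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            confusion_metrics(np.array([[1, -1], [0, 1]]))

    def test_confusion_matrix_convention(self):
        # rows = actual, columns = predicted
        cm = confusion_matrix(np.array([0, 0, 1]), np.array([1, 0, 1]), 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])


class TestKfold:
    def test_each_sample_in_one_test_fold(self, blob_matrix):
        folds = stratified_folds(blob_matrix.y, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(60))

    def test_cvp_is_fold_mean(self):
        accs = [1.0, 0.8, 0.9, 1.0, 0.8]
        assert np.mean(accs) == pytest.approx(0.9)

    def test_blobs_recovered(self, blob_matrix):
        report = kfold_evaluate(
            blob_matrix, [ClassifierSpec(name="RandomForest")], k=5, seed=42, smote_mode="guarded"
        )
        assert report.cv["RandomForest"]["accuracy"] >= 0.95
        assert len(report.folds) == 5
        for f in report.folds:
            assert f.cm.sum() == f.n_test

    def test_guarded_mode_ignores_test_labels(self, blob_matrix):
        def run(data):
            rep = kfold_evaluate(data, [ClassifierSpec(name="KNN")], k=3, seed=1)
            return [f.cm for f in rep.folds]

        mutated = FeatureMatrix(
            blob_matrix.X.copy(), blob_matrix.y.copy(), list(blob_matrix.class_names)
        )
        base_folds = stratified_folds(blob_matrix.y, 3, seed=1)
        victim = base_folds[0][0]
        run(blob_matrix)  # baseline for reference below

        # mutating one test sample's features must not change other rows'
        # predictions in its fold (training never saw it)
        m1 = kfold_evaluate(blob_matrix, [ClassifierSpec(name="KNN")], k=3, seed=1)
        mutated.X[victim] += 100.0
        m2 = kfold_evaluate(mutated, [ClassifierSpec(name="KNN")], k=3, seed=1)
        # at most the victim's own prediction differs in fold 0
        assert abs(m1.folds[0].cm.sum() - m2.folds[0].cm.sum()) == 0
        diff = np.abs(m1.folds[0].cm - m2.folds[0].cm).sum()
        assert diff <= 2  # one sample moving between cells

    def test_invalid_k(self, blob_matrix):
        with pytest.raises(ValueError):
            kfold_evaluate(blob_matrix, [ClassifierSpec(name="KNN")], k=1)
        with pytest.raises(ValueError):
            kfold_evaluate(blob_matrix, [ClassifierSpec(name="KNN")], k=61)

    def test_report_serializes(self, blob_matrix):
        report = kfold_evaluate(blob_matrix, [ClassifierSpec(name="KNN")], k=3, seed=1)
        d = report.to_dict()
        assert len(d["folds"]) == 3
        assert "KNN" in d["cv"]
        import json

        json.dumps(d)  # must be JSON-serializable
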