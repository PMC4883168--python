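import numpy as np
import pytest
from sklearn import metrics as skm

from eegoat import evaluation as ev
from eegoat.classifiers import ClassifierSpec
from eegoat.eeg_io import FeatureMatrix, FEATURE_NAMES
from eegoat.exceptions import ValidationError

from conftest import TABLE2_CONFUSION, TABLE4_CONFUSION

CLASSES = ["healthy", "seizure-free", "seizure"]


def _fm_from_X(X, y):
    X = np.asarray(X)
    if X.shape[1] < len(FEATURE_NAMES):
        X = np.hstack([X, np.zeros((X.shape[0], len(FEATURE_NAMES) - X.shape[1]))])
    return FeatureMatrix.from_arrays(X, y, ["S"] * len(y))


class TestFolds:
    def test_balanced_ten_fold(self):
        labels = np.repeat(CLASSES, 100)
        plan = ev.make_stratified_folds(labels, 10, seed=0)
        for fold in plan.folds:
            assert fold.size == 30
            values, counts = np.unique(labels[fold], return_counts=True)
            assert list(counts) == [10, 10, 10]

    def test_single_fold_is_everything(self):
        plan = ev.make_stratified_folds(["a", "b", "a"], 1, seed=0)
        np.testing.assert_array_equal(plan.folds[0], [0, 1, 2])

    def test_folds_partition_indices(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(CLASSES, size=83)
        k = int(min(np.unique(labels, return_counts=True)[1]))
        plan = ev.make_stratified_folds(labels, k, seed=3)
        joined = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(joined, np.arange(83))

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError):
            ev.make_stratified_folds(["a"] * 10 + ["b"] * 3, 5, seed=0)

    def test_deterministic(self):
        labels = np.repeat(CLASSES, 20)
        p1 = ev.make_stratified_folds(labels, 5, seed=7)
        p2 = ev.make_stratified_folds(labels, 5, seed=7)
        for a, b in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(a, b)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(CLASSES, 4)
        cm = ev.confusion_from_predictions(y, y, classes=CLASSES)
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int) * 4)

    def test_single_predicted_class_single_column(self):
        y = np.repeat(CLASSES, 2)
        pred = np.array(["seizure"] * 6)
        cm = ev.confusion_from_predictions(y, pred, classes=CLASSES)
        assert cm.counts[:, 2].sum() == 6 == cm.total

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            ev.confusion_from_predictions(["healthy"], ["unknown"], classes=CLASSES)


class TestMetricArithmetic:
    def test_published_lmt_table_reconstruction(self):
        """The confusion matrix implied by the published LMT per-class
        numbers reproduces its sensitivity/specificity/precision/F and the
        95.33% overall accuracy."""
        cm = ev.ConfusionMatrix(TABLE2_CONFUSION, CLASSES)
        healthy = ev.class_metrics(cm, "healthy")
        assert 100 * healthy["sensitivity"] == pytest.approx(95.0)
        assert 100 * healthy["specificity"] == pytest.approx(97.0)
        assert 100 * healthy["precision"] == pytest.approx(94.1, abs=0.05)
        assert 100 * healthy["f_measure"] == pytest.approx(94.5, abs=0.1)
        seizure = ev.class_metrics(cm, "seizure")
        assert 100 * seizure["sensitivity"] == pytest.approx(99.0)
        assert 100 * seizure["specificity"] == pytest.approx(99.0)
        assert np.trace(cm.counts) / cm.total == pytest.approx(0.9533, abs=5e-5)

    def test_published_svm_table_reconstruction(self):
        cm = ev.ConfusionMatrix(TABLE4_CONFUSION, CLASSES)
        assert np.trace(cm.counts) / cm.total == pytest.approx(0.36)
        seizure = ev.class_metrics(cm, "seizure")
        assert 100 * seizure["precision"] == pytest.approx(34.2, abs=0.05)
        healthy = ev.class_metrics(cm, "healthy")
        assert healthy["specificity"] == 1.0 and healthy["precision"] == 1.0

    def test_perfect_matrix_all_metrics_unity(self):
        cm = ev.ConfusionMatrix(np.eye(3, dtype=int) * 10, CLASSES)
        for c in CLASSES:
            m = ev.class_metrics(cm, c)
            assert (m["sensitivity"], m["specificity"], m["precision"],
                    m["f_measure"]) == (1, 1, 1, 1)

    def test_zero_division_flagged(self):
        counts = np.array([[5, 0, 0], [5, 0, 0], [5, 0, 0]])
        m = ev.class_metrics(ev.ConfusionMatrix(counts, CLASSES), "seizure")
        assert m["undefined"] and m["precision"] == 0.0

    def test_kappa_limits(self):
        perfect = ev.ConfusionMatrix(np.eye(2, dtype=int) * 50, ["a", "b"])
        y = ["a"] * 50 + ["b"] * 50
        proba = np.array([[1.0, 0.0]] * 50 + [[0.0, 1.0]] * 50)
        assert ev.overall_metrics(perfect, proba, y)["kappa"] == pytest.approx(1.0)
        chance = ev.ConfusionMatrix([[25, 25], [25, 25]], ["a", "b"])
        proba2 = np.tile([0.5, 0.5], (100, 1))
        assert ev.overall_metrics(chance, proba2, y)["kappa"] == pytest.approx(0.0)

    def test_mae_hand_example(self):
        """Balanced 3 classes, everything predicted as one class with hard
        probabilities → accuracy 1/3 and MAE 4/9."""
        y = np.repeat(CLASSES, 10)
        pred = np.array(["healthy"] * 30)
        cm = ev.confusion_from_predictions(y, pred, classes=CLASSES)
        proba = np.tile([1.0, 0.0, 0.0], (30, 1))
        out = ev.overall_metrics(cm, proba, y)
        assert out["accuracy"] == pytest.approx(1 / 3)
        assert out["mae"] == pytest.approx(4 / 9)


class TestOracleEquivalence:
    """Hand-rolled metrics must agree with scikit-learn to 1e−9."""

    def test_confusion_metrics_match_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(10, 60)
            y = rng.choice(CLASSES, size=n)
            pred = rng.choice(CLASSES, size=n)
            cm = ev.confusion_from_predictions(y, pred, classes=CLASSES)
            labels = CLASSES
            sens = skm.recall_score(
                y, pred, labels=labels, average=None, zero_division=0
            )
            prec = skm.precision_score(
                y, pred, labels=labels, average=None, zero_division=0
            )
            f1 = skm.f1_score(y, pred, labels=labels, average=None, zero_division=0)
            for j, c in enumerate(labels):
                m = ev.class_metrics(cm, c)
                assert m["sensitivity"] == pytest.approx(sens[j], abs=1e-9)
                assert m["precision"] == pytest.approx(prec[j], abs=1e-9)
                assert m["f_measure"] == pytest.approx(f1[j], abs=1e-9)
            proba = rng.dirichlet([1, 1, 1], size=n)
            out = ev.overall_metrics(cm, proba, y)
            assert out["accuracy"] == pytest.approx(
                skm.accuracy_score(y, pred), abs=1e-9
            )
            assert out["kappa"] == pytest.approx(
                skm.cohen_kappa_score(y, pred, labels=labels), abs=1e-9
            )

    def test_roc_auc_matches_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(10, 80)
            pos = rng.random(n) < 0.4
            if pos.all() or not pos.any():
                continue
            scores = np.round(rng.random(n), 2)  # ties included
            mine = ev.roc_auc_ovr(scores, pos)
            ref = skm.roc_auc_score(pos, scores)
            assert mine == pytest.approx(ref, abs=1e-9)


class TestCrossValidation:
    def test_separable_features_are_perfect(self, small_feature_matrix):
        report = ev.cross_validate(
            small_feature_matrix, ClassifierSpec("MLR"), k=5, seed=0
        )
        assert report.overall["accuracy_pct"] == 100.0
        assert report.overall["kappa"] == pytest.approx(1.0)
        assert report.overall["mae"] < 0.05

    def test_deterministic_reports(self, small_feature_matrix):
        r1 = ev.cross_validate(small_feature_matrix, ClassifierSpec("MLR"), k=5, seed=4)
        r2 = ev.cross_validate(small_feature_matrix, ClassifierSpec("MLR"), k=5, seed=4)
        assert r1.to_dict() == r2.to_dict()

    def test_pooled_accuracy_is_weighted_fold_mean(self, small_feature_matrix):
        fm = small_feature_matrix
        seed = 2
        report = ev.cross_validate(fm, ClassifierSpec("MLR"), k=5, seed=seed)
        # recompute per-fold accuracies with the identical plan and seeds
        from eegoat.classifiers import fit_model

        plan = ev.make_stratified_folds(fm.labels, 5, seed)
        fold_seeds = (
            np.random.SeedSequence(entropy=seed, spawn_key=(1,)).generate_state(5)
            % 2**31
        ).tolist()
        accs, sizes = [], []
        for i, test_idx in enumerate(plan.folds):
            mask = np.ones(fm.n_rows, dtype=bool)
            mask[test_idx] = False
            model = fit_model(
                ClassifierSpec("MLR"), fm.X[mask], fm.labels[mask], seed=fold_seeds[i]
            )
            accs.append(np.mean(model.predict(fm.X[test_idx]) == fm.labels[test_idx]))
            sizes.append(test_idx.size)
        pooled = np.sum(np.array(accs) * np.array(sizes)) / np.sum(sizes)
        assert report.overall["accuracy_pct"] == pytest.approx(100 * pooled, abs=1e-9)

    def test_label_shuffle_gives_chance_accuracy(self, small_feature_matrix):
        """Permutation null: ~33% accuracy on 3 balanced classes."""
        fm = small_feature_matrix
        accs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            shuffled = FeatureMatrix.from_arrays(
                fm.X, rng.permutation(fm.labels), fm.sets
            )
            rep = ev.cross_validate(shuffled, ClassifierSpec("MLR"), k=5, seed=s)
            accs.append(rep.overall["accuracy_pct"])
        assert abs(np.mean(accs) - 100 / 3) < 8


class TestRepeats:
    def test_single_repeat_matches_cross_validate(self, small_feature_matrix):
        fm = small_feature_matrix
        base_seed = 5
        seed0 = int(
            np.random.SeedSequence(entropy=base_seed).generate_state(1)[0] % 2**31
        )
        single = ev.cross_validate(fm, ClassifierSpec("MLR"), k=5, seed=seed0)
        repeated = ev.repeat_experiment(
            fm, ClassifierSpec("MLR"), k=5, n_repeats=1, base_seed=base_seed
        )
        assert repeated.overall == single.overall

    def test_mean_lies_within_repeat_range(self, small_feature_matrix):
        report = ev.repeat_experiment(
            small_feature_matrix, ClassifierSpec("MLR"), k=5, n_repeats=4, base_seed=1
        )
        accs = [r["accuracy_pct"] for r in report.per_repeat]
        assert min(accs) <= report.overall["accuracy_pct"] <= max(accs)
        assert set(report.std) == set(report.overall) or report.std is not None

    def test_report_export(self, small_feature_matrix, tmp_path):
        report = ev.repeat_experiment(
            small_feature_matrix, ClassifierSpec("MLR"), k=5, n_repeats=2, base_seed=0
        )
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        text = (tmp_path / "r.csv").read_text()
        assert "sensitivity_pct" in text and "Overall" in text
        assert (tmp_path / "r.json").stat().st_size > 0
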