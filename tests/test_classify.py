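"""Bagged ensemble, cross-validation bookkeeping, ROC, comparison harness."""

import numpy as np
import pytest
from _oracles import auc_pairwise
from sklearn.tree import DecisionTreeClassifier

from wearsense import (BaggedTreesClassifier, compare_classifiers,
                       repeated_kfold_cv, roc_auc_ovr, train_bagged_trees)
from wearsense.classify import load_model, predict, save_model
from wearsense.exceptions import ParameterError


def two_clusters(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 4)), rng.normal(5, 0.3, (n // 2, 4))])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return X, y


def three_clusters(n_per=20, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(i * sep, 0.5, (n_per, 5)) for i in range(3)])
    y = np.array(["flapping"] * n_per + ["painting"] * n_per + ["sibbing"] * n_per)
    return X, y


class TestBaggedTrees:
    def test_separable_clusters_reach_training_accuracy_one(self):
        X, y = two_clusters()
        model = train_bagged_trees(X, y, n_trees=5, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_exactly_n_trees_fitted(self):
        X, y = two_clusters()
        model = train_bagged_trees(X, y, n_trees=7, seed=0)
        assert len(model.trees_) == 7

    def test_same_seed_gives_identical_predictions(self):
        X, y = three_clusters()
        probe = np.random.default_rng(5).normal(3, 4, (10, 5))
        p1 = train_bagged_trees(X, y, n_trees=10, seed=3).predict(probe)
        p2 = train_bagged_trees(X, y, n_trees=10, seed=3).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_single_tree_without_bootstrap_equals_plain_tree(self):
        X, y = three_clusters(seed=2)
        probe = np.random.default_rng(8).normal(3, 5, (20, 5))
        bag = BaggedTreesClassifier(n_trees=1, bootstrap=False, random_state=0).fit(X, y)
        seed = bag.trees_[0].random_state
        plain = DecisionTreeClassifier(criterion="gini", random_state=seed).fit(X, y)
        np.testing.assert_array_equal(bag.predict(probe), plain.predict(probe))

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 3))
        y = np.array(["a"] * 10)
        with pytest.raises(ParameterError, match="single class"):
            train_bagged_trees(X, y)

    def test_column_mismatch_rejected(self):
        X, y = two_clusters()
        model = train_bagged_trees(X, y, n_trees=3, seed=0)
        with pytest.raises(ParameterError, match="columns"):
            model.predict(np.zeros((2, 7)))

    def test_vote_fractions_match_per_tree_counts(self):
        X, y = three_clusters(seed=4)
        model = train_bagged_trees(X, y, n_trees=9, seed=1)
        probe = np.random.default_rng(2).normal(4, 6, (3, 5))
        _, frac = predict(model, probe)
        counts = np.zeros_like(frac)
        col = {c: j for j, c in enumerate(model.classes_)}
        for tree in model.trees_:
            for i, p in enumerate(tree.predict(probe)):
                counts[i, col[p]] += 1
        np.testing.assert_allclose(frac, counts / 9)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)

    def test_unanimous_vote_fraction_is_one(self):
        X, y = two_clusters(seed=1)
        model = train_bagged_trees(X, y, n_trees=6, seed=0)
        frac = model.predict_proba(X[:3])
        assert np.all(frac.max(axis=1) == 1.0)

    def test_tied_votes_break_to_first_class_in_order(self):
        class ConstTree:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.array([self.label] * len(X))

        model = BaggedTreesClassifier(n_trees=2)
        model.classes_ = np.array(["flapping", "painting", "sibbing"])
        model.trees_ = [ConstTree("painting"), ConstTree("flapping")]
        model.n_features_in_ = 2
        pred = model.predict(np.zeros((4, 2)))
        assert list(pred) == ["flapping"] * 4  # 1-1-0 tie -> first in class order

    def test_sklearn_get_set_params_round_trip(self):
        model = BaggedTreesClassifier(n_trees=13, bootstrap=False)
        params = model.get_params()
        assert params["n_trees"] == 13
        clone_params = BaggedTreesClassifier().set_params(**params).get_params()
        assert clone_params == params


class TestRepeatedKFoldCV:
    def test_leave_one_out_fold_structure(self):
        X, y = two_clusters(n=12, seed=3)
        report = repeated_kfold_cv(X, y, K=6, n_repeats=1, n_trees=3, seed=0)
        folds = [idx for _, _, idx in report.per_fold_indices]
        assert len(folds) == 6
        assert sorted(np.concatenate(folds).tolist()) == list(range(12))

    def test_fold_sizes_for_165_samples_are_16_or_17(self):
        X, y = three_clusters(n_per=55, seed=0)
        report = repeated_kfold_cv(X, y, K=10, n_repeats=1, n_trees=2, seed=0)
        sizes = sorted(len(idx) for _, _, idx in report.per_fold_indices)
        assert set(sizes) <= {16, 17}
        assert sum(sizes) == 165

    def test_separable_data_gives_diagonal_confusion(self):
        X, y = three_clusters(n_per=20, sep=8.0, seed=1)
        report = repeated_kfold_cv(X, y, K=5, n_repeats=2, n_trees=10, seed=0)
        assert report.overall_accuracy == 1.0
        assert np.all(report.confusion == np.diag(np.diag(report.confusion)))

    def test_confusion_pooling_conservation(self):
        X, y = three_clusters(n_per=12, sep=2.0, seed=5)
        n_repeats = 3
        report = repeated_kfold_cv(X, y, K=4, n_repeats=n_repeats, n_trees=5, seed=1)
        assert report.confusion.sum() == len(y) * n_repeats
        np.testing.assert_array_equal(report.confusion.sum(axis=1), 12 * n_repeats)

    def test_overall_accuracy_equals_trace_over_sum(self):
        X, y = three_clusters(n_per=12, sep=1.0, seed=6)
        report = repeated_kfold_cv(X, y, K=4, n_repeats=2, n_trees=5, seed=2)
        assert report.overall_accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum(), abs=1e-12)
        assert report.overall_accuracy == pytest.approx(
            report.per_repeat_accuracy.mean(), abs=1e-12)

    def test_class_smaller_than_K_rejected(self):
        X, y = three_clusters(n_per=5, seed=0)
        with pytest.raises(ParameterError, match="smaller K"):
            repeated_kfold_cv(X, y, K=10, n_repeats=1)


class TestROC:
    def test_perfect_scores_give_auc_one(self):
        y = np.array(["a", "a", "b", "b", "c"])
        order = ["a", "b", "c"]
        scores = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], float)
        macro, curves = roc_auc_ovr(y, scores, order)
        assert macro == 1.0
        assert all(a == 1.0 for _, _, a in curves.values())

    def test_constant_scores_give_auc_half(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        scores = np.full((10, 2), 0.5)
        macro, _ = roc_auc_ovr(y, scores, ["a", "b"])
        assert macro == pytest.approx(0.5)

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        y = np.array(["x"] * 6 + ["y"] * 4)
        scores = rng.random((10, 2))
        scores /= scores.sum(axis=1, keepdims=True)
        macro, curves = roc_auc_ovr(y, scores, ["x", "y"])
        for j, cls in enumerate(["x", "y"]):
            expected = auc_pairwise(y == cls, scores[:, j])
            assert curves[cls][2] == pytest.approx(expected)

    def test_absent_class_excluded_with_warning(self):
        y = np.array(["a", "a", "b", "b"])
        scores = np.random.default_rng(1).random((4, 3))
        with pytest.warns(UserWarning, match="absent"):
            macro, curves = roc_auc_ovr(y, scores, ["a", "b", "c"])
        assert "c" not in curves
        assert np.isfinite(macro)


@pytest.fixture(scope="module")
def table(small_feature_dataset):
    X, y = small_feature_dataset
    return compare_classifiers(X, y, K=4, seed=0)


class TestComparisonHarness:
    def test_six_rows(self, table):
        assert len(table) == 6
        assert set(table["model"]) == {
            "complex_tree", "simple_tree", "linear_svm", "gaussian_svm",
            "boosted_trees", "bagged_trees"}

    def test_identical_folds_across_models(self, table):
        assert table["fold_hash"].nunique() == 1

    def test_bagged_not_outperformed_by_simple_tree(self, table):
        acc = dict(zip(table["model"], table["accuracy"]))
        assert acc["bagged_trees"] >= acc["simple_tree"]

    def test_all_metrics_in_range(self, table):
        assert ((table["accuracy"] >= 0) & (table["accuracy"] <= 1)).all()
        assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()


class TestNoiseTrend:
    def test_raising_sensor_noise_does_not_raise_accuracy(self):
        """Mean CV accuracy is non-increasing as noise_sd goes 0.3 -> 3.0."""
        from wearsense import feature_matrix, generate_dataset, segment_windows

        means = []
        for noise in (0.3, 1.5, 3.0):
            accs = []
            for seed in (1, 2, 3):
                recs = generate_dataset(n_per_class=15, duration=2.0,
                                        n_subjects=5, seed=seed, noise_sd=noise)
                wins = [w for r in recs for w in segment_windows(r)]
                X, y = feature_matrix(wins)
                rep = repeated_kfold_cv(X, np.asarray(y), K=5, n_repeats=1,
                                        n_trees=15, seed=seed)
                accs.append(rep.overall_accuracy)
            means.append(np.mean(accs))
        assert means[0] >= means[1] >= means[2]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = two_clusters(seed=7)
        model = train_bagged_trees(X, y, n_trees=4, seed=0)
        p = tmp_path / "model.joblib"
        save_model(model, p)
        back = load_model(p)
        np.testing.assert_array_equal(back.predict(X), model.predict(X))

    def test_mismatched_manifest_refused(self, tmp_path):
        import joblib

        X, y = two_clusters(seed=7)
        model = train_bagged_trees(X, y, n_trees=2, seed=0)
        p = tmp_path / "model.joblib"
        joblib.dump({"model": model, "manifest_version": "0.0",
                     "feature_names": ["bogus"]}, p)
        with pytest.raises(ParameterError, match="manifest"):
            load_model(p)
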