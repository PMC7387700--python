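import numpy as np
import pytest

from phlastab import (
    StablePeptideClassifier,
    balanced_weights,
    evaluate_cv,
    evaluate_loao,
    feature_importance,
    predict_phla,
    roc_auc,
)
from phlastab.dataset import TrainingMatrix
from phlastab.models import _max_features_log2floor

from ._oracles import mann_whitney_auc


class TestClassifierDefaults:
    def test_seven_candidate_features_for_210(self, small_forest):
        assert _max_features_log2floor(210) == 7
        assert small_forest.estimator_.max_features == 7

    def test_default_hyperparameters(self):
        clf = StablePeptideClassifier()
        assert clf.model == "rf"
        assert clf.n_estimators == 1000
        assert clf.criterion == "gini"

    def test_rejects_single_class_and_nan(self):
        X = np.random.default_rng(0).random((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            StablePeptideClassifier(n_estimators=5).fit(X, np.zeros(10))
        Xn = X.copy(); Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            StablePeptideClassifier(n_estimators=5).fit(Xn, np.arange(10) % 2)

    def test_unknown_model_kind(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            StablePeptideClassifier(model="svm").fit(np.eye(4), [0, 1, 0, 1])

    def test_seeded_determinism(self, small_matrix):
        preds = []
        for _ in range(2):
            clf = StablePeptideClassifier(n_estimators=30, random_state=7).fit(
                small_matrix.X, small_matrix.y
            )
            preds.append(clf.predict_proba(small_matrix.X[:20]))
        np.testing.assert_array_equal(preds[0], preds[1])

    @pytest.mark.parametrize("kind", ["gb", "lr"])
    def test_baseline_models_fit_and_predict(self, small_matrix, kind):
        clf = StablePeptideClassifier(model=kind, n_estimators=20).fit(
            small_matrix.X, small_matrix.y
        )
        proba = clf.predict_proba(small_matrix.X[:5])
        assert proba.shape == (5, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)


class TestEnsemblePrediction:
    def test_probability_is_arithmetic_mean(self, small_forest, small_matrix):
        X = small_matrix.X[:3]
        per_conf = small_forest.predict_proba(X)[:, 1]
        assert small_forest.predict_phla(X) == pytest.approx(per_conf.mean())

    def test_single_conformation_identity(self, small_forest, small_matrix):
        x = small_matrix.X[0]
        assert small_forest.predict_phla(x[None, :]) == pytest.approx(
            small_forest.predict_proba(x[None, :])[0, 1]
        )

    def test_identical_conformations_equal_one(self, small_forest, small_matrix):
        x = small_matrix.X[0]
        stacked = np.tile(x, (5, 1))
        assert small_forest.predict_phla(stacked) == pytest.approx(
            small_forest.predict_phla(x[None, :])
        )

    def test_empty_list_rejected(self, small_forest):
        with pytest.raises(ValueError):
            predict_phla(small_forest, [])


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert roc_auc([0, 1], [0.2, 0.8]) == 1.0
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([1, 1], [0.2, 0.8])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # discretized scores so ties actually occur
        scores = np.round(rng.random(n), 1)
        assert roc_auc(labels, scores) == pytest.approx(
            mann_whitney_auc(labels, scores), abs=1e-12
        )


class TestCrossValidation:
    def test_planted_signal_recovered(self, small_matrix):
        report = evaluate_cv(small_matrix, "rf", k=5, seed=0, n_estimators=100)
        assert report.mean > 0.9
        assert all(0.0 <= a <= 1.0 for a in report.aurocs.values())

    def test_grouped_folds_do_not_split_phlas(self, small_matrix):
        from sklearn.model_selection import GroupKFold

        splitter = GroupKFold(n_splits=5, shuffle=True, random_state=0)
        for train, test in splitter.split(
            small_matrix.X, small_matrix.y, groups=small_matrix.groups
        ):
            assert not (
                set(small_matrix.groups[train]) & set(small_matrix.groups[test])
            )

    def test_shuffled_labels_near_chance(self, small_matrix):
        rng = np.random.default_rng(0)
        y = rng.permutation(small_matrix.y)
        shuffled = TrainingMatrix(
            X=small_matrix.X, y=y, groups=small_matrix.groups,
            alleles=small_matrix.alleles,
            sample_weight=balanced_weights(y), mode="ensemble",
        )
        report = evaluate_cv(shuffled, "rf", k=5, seed=0, n_estimators=60)
        assert 0.25 < report.mean < 0.75

    def test_two_folds_on_four_groups(self):
        rng = np.random.default_rng(1)
        X = rng.random((8, 210))
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        groups = np.array(["g1", "g1", "g2", "g2", "g3", "g3", "g4", "g4"], dtype=object)
        m = TrainingMatrix(
            X=X, y=y, groups=groups, alleles=np.array(["a"] * 8, dtype=object),
            sample_weight=balanced_weights(y),
        )
        report = evaluate_cv(m, "rf", k=2, seed=0, n_estimators=5)
        assert len(report.aurocs) + len(report.skipped) == 2

    def test_needs_two_folds(self, small_matrix):
        with pytest.raises(ValueError):
            evaluate_cv(small_matrix, "rf", k=1)


class TestLeaveOneAlleleOut:
    def test_one_auroc_per_two_class_allele(self, small_matrix):
        report = evaluate_loao(small_matrix, "rf", seed=0, n_estimators=100)
        assert set(report.aurocs) == set(np.unique(small_matrix.alleles))
        assert report.mean > 0.9
        assert report.config["protocol"] == "loao"

    def test_single_class_allele_skipped(self, small_matrix):
        m = small_matrix
        # make one allele all-positive by dropping its negatives
        allele = np.unique(m.alleles)[0]
        keep = ~((m.alleles == allele) & (m.y == 0))
        y = m.y[keep]
        reduced = TrainingMatrix(
            X=m.X[keep], y=y, groups=m.groups[keep], alleles=m.alleles[keep],
            sample_weight=balanced_weights(y),
        )
        report = evaluate_loao(reduced, "rf", seed=0, n_estimators=20)
        assert str(allele) in report.skipped
        assert "class" in report.skipped[str(allele)]

    def test_single_allele_rejected(self, small_matrix):
        m = small_matrix
        one = m.alleles == np.unique(m.alleles)[0]
        y = m.y[one]
        single = TrainingMatrix(
            X=m.X[one], y=y, groups=m.groups[one], alleles=m.alleles[one],
            sample_weight=balanced_weights(y),
        )
        with pytest.raises(ValueError, match="2 alleles"):
            evaluate_loao(single, "rf")


class TestFeatureImportance:
    def test_normalized_and_nonnegative(self, small_forest):
        imp = feature_importance(small_forest)
        assert imp.shape == (210,)
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_features_top_ranked(self, small_planted, small_forest):
        spec, data = small_planted
        top5 = set(np.argsort(-feature_importance(small_forest))[:5])
        assert set(data.manifest["signal_feature_indices"]) <= top5

    def test_label_independent_noise_near_uniform(self):
        rng = np.random.default_rng(0)
        X = rng.random((300, 40))
        y = rng.integers(0, 2, 300)
        clf = StablePeptideClassifier(n_estimators=200, random_state=0).fit(X, y)
        imp = feature_importance(clf)
        assert imp.max() < 3.0 / 40

    def test_lr_has_no_impurity_importance(self, small_matrix):
        clf = StablePeptideClassifier(model="lr").fit(small_matrix.X, small_matrix.y)
        with pytest.raises(ValueError, match="importances"):
            feature_importance(clf)
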