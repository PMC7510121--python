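import itertools

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.estimator_checks import check_estimator

from beadquant.classify import (
    MODEL_NAMES,
    SubspaceDiscriminantEnsemble,
    cross_validate,
    fit_classifier,
    pca_summary,
    roc_from_scores,
    stepwise_logistic,
)
from beadquant.errors import ParameterError


def _separable_data(n=60, d=46, gap=6.0, seed=0, n_signal=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", :n_signal] += gap
    return X, y


def _noise_data(n=100, d=46, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, d)), np.array(["a", "b"] * (n // 2))


class TestSDE:
    def test_single_learner_full_subspace_equals_lda(self):
        X, y = _noise_data(n=80, d=10, seed=1)
        y = (np.arange(80) % 2).astype(int)
        X[y == 1, 3] += 1.0
        sde = SubspaceDiscriminantEnsemble(n_estimators=1, subspace_dim=10, random_state=0).fit(X, y)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_array_equal(sde.predict(X), lda.predict(X))

    def test_deterministic_given_seed(self):
        X, y = _separable_data(seed=2)
        a = SubspaceDiscriminantEnsemble(random_state=42).fit(X, y)
        b = SubspaceDiscriminantEnsemble(random_state=42).fit(X, y)
        Xt = np.random.default_rng(0).normal(size=(20, 46))
        np.testing.assert_array_equal(a.predict(Xt), b.predict(Xt))
        for (ia, _), (ib, _) in zip(a.estimators_, b.estimators_):
            np.testing.assert_array_equal(ia, ib)

    def test_sklearn_estimator_contract(self):
        check_estimator(SubspaceDiscriminantEnsemble(n_estimators=5, random_state=0))

    def test_singular_subspace_handled_by_shrinkage(self):
        # duplicated feature makes the within-class covariance singular
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        X = np.hstack([X, X[:, :1]])
        y = (X[:, 0] > 0).astype(int)
        sde = SubspaceDiscriminantEnsemble(n_estimators=10, subspace_dim=3, random_state=0)
        sde.fit(X, y)  # must not raise nor drop learners
        assert len(sde.estimators_) == 10


class TestClassifiers:
    def test_large_margin_all_models_perfect_training(self):
        # one strongly informative metric among a few nuisance metrics
        # (distance-based KNN needs the margin to dominate the metric space)
        X, y = _separable_data(d=6, gap=10.0)
        for name in MODEL_NAMES:
            model = fit_classifier(X, y, name, seed=0)
            assert np.mean(model.predict(X) == y) == 1.0, name

    def test_knn_k1_memorizes_distinct_points(self):
        X, y = _separable_data(gap=1.0)
        model = fit_classifier(X, y, "knn", hyperparams={"n_neighbors": 1}, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_permuted_labels_give_chance_cv(self):
        X, _ = _noise_data(n=100, seed=3)
        rng = np.random.default_rng(3)
        y = rng.permutation(np.array(["a", "b"] * 50))
        for name in MODEL_NAMES:
            rep = cross_validate(X, y, name, k=5, seed=3)
            sd = np.sqrt(0.25 / 100)
            assert abs(rep.cv_accuracy - 0.5) <= 3 * sd + 0.05

    def test_needs_two_classes(self):
        X = np.zeros((10, 4))
        with pytest.raises(ParameterError):
            fit_classifier(X, np.array(["a"] * 10), "svm")


class TestCrossValidation:
    def test_separable_classes_cv_perfect(self):
        X, y = _separable_data(gap=2.0, n_signal=46)
        rep = cross_validate(X, y, "svm", k=5, seed=0)
        assert rep.cv_accuracy == 1.0
        assert len(rep.per_fold) == 5

    def test_stratification_contract(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array(["a"] * 18 + ["b"] * 27)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        sizes = []
        for _, test_idx in skf.split(np.zeros((45, 1)), y):
            sizes.append(len(test_idx))
            frac_a = np.mean(y[test_idx] == "a")
            assert abs(frac_a * len(test_idx) - 18 / 45 * len(test_idx)) <= 1
        assert max(sizes) - min(sizes) <= 1

    def test_k_larger_than_class_rejected(self):
        X, y = _separable_data(n=12)
        with pytest.raises(ParameterError):
            cross_validate(X, y, "svm", k=7, seed=0)

    def test_deterministic_reports(self):
        X, y = _separable_data(gap=1.0, seed=5)
        a = cross_validate(X, y, "sde", k=5, seed=9)
        b = cross_validate(X, y, "sde", k=5, seed=9)
        assert a.per_fold == b.per_fold and a.cv_accuracy == b.cv_accuracy

    def test_validation_set_scored_separately(self):
        X, y = _separable_data(gap=2.0, seed=0, n_signal=46)
        Xv, yv = _separable_data(n=20, gap=2.0, seed=1, n_signal=46)
        rep = cross_validate(X, y, "logistic", k=5, seed=0, X_val=Xv, y_val=yv)
        assert rep.validation_accuracy == 1.0
        assert rep.auc == 1.0


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.array([0] * 5 + [1] * 5)
        scores = np.arange(10, dtype=float)
        pts, auc = roc_from_scores(y, scores)
        assert auc == pytest.approx(1.0)
        fprs = [p[0] for p in pts]
        assert fprs == sorted(fprs)

    def test_label_independent_scores_auc_half(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 100)
        scores = rng.normal(size=200)
        _, auc = roc_from_scores(y, scores)
        assert abs(auc - 0.5) <= 3 * np.sqrt(1 / 12 * (1 / 100 + 1 / 100))  # ~3 SE of U/(n+n-)

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = int(rng.integers(3, 25)), int(rng.integers(3, 25))
        y = np.array([0] * n_neg + [1] * n_pos)
        scores = np.round(rng.normal(size=n_pos + n_neg), 2)  # ties likely
        _, auc = roc_from_scores(y, scores)
        pos = scores[y == 1]
        neg = scores[y == 0]
        u = sum((1.0 if p > n else 0.5 if p == n else 0.0)
                for p, n in itertools.product(pos, neg))
        assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_single_class_undefined(self):
        pts, auc = roc_from_scores(np.ones(5), np.arange(5.0))
        assert pts == [] and np.isnan(auc)


class TestPCA:
    def test_variance_fractions_sum_to_one(self):
        X = np.random.default_rng(0).normal(size=(50, 8))
        summary = pca_summary(X)
        assert summary.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(summary.variance_fractions) <= 1e-12)

    def test_perfectly_correlated_features_rank_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        X = np.column_stack([a, 3 * a + 1])
        summary = pca_summary(X)
        assert summary.variance_fractions[0] == pytest.approx(1.0)

    def test_isotropic_null_first_two_components(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 46))
        summary = pca_summary(X)
        first_two = summary.variance_fractions[:2].sum()
        # null expectation 2/46 plus Marchenko-Pastur inflation at n=150, d=46
        assert 2 / 46 < first_two < 0.25

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning):
            summary = pca_summary(X)
        assert summary.kept_features == [0, 1, 3]


class TestStepwise:
    def _planted(self, seed, signal_cols, n=80, beta=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 46))
        logit = sum(beta * X[:, j] for j in signal_cols)
        p = 1 / (1 + np.exp(-logit))
        y = (rng.uniform(size=n) < p).astype(int)
        return X, y

    def test_planted_single_signal_recovered(self):
        hits = 0
        for seed in range(20):
            X, y = self._planted(seed, [16])  # m17 is column index 16
            selected, _ = stepwise_logistic(X, y)
            hits += 16 in selected
        assert hits >= 18  # >= 90% recovery

    def test_two_planted_signals_recovered_first(self):
        X, y = self._planted(4, [15, 20], n=150, beta=2.5)  # m16 and m21
        selected, result = stepwise_logistic(X, y)
        assert 15 in selected and 20 in selected
        # the planted signals dominate every noise feature, so they enter
        # before any spurious addition
        assert set(selected[:2]) == {15, 20}
        assert result is not None

    def test_pure_noise_selects_at_aic_false_inclusion_rate(self):
        # scanning 46 candidates per step inflates AIC's per-feature
        # chi2_1 > 2 false-inclusion rate (~0.16); the selection still
        # stays well below half the feature set
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 46))
        y = rng.integers(0, 2, size=80)
        selected, _ = stepwise_logistic(X, y)
        assert len(selected) <= 20

    def test_small_sample_rejected(self):
        X = np.zeros((8, 46))
        y = np.array([0, 1] * 4)
        with pytest.raises(ParameterError):
            stepwise_logistic(X, y)
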