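"""Pseudolinear LDA, one-vs-one ECOC, F1 scoring and split evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from scdecode.decoder import (
    confusion_matrix,
    evaluate_window,
    fit_binary_lda,
    fit_ecoc,
    per_class_f1,
    predict_ecoc,
)


def brute_force_f1(y_true, y_pred, n_classes=8):
    """Independent per-class F1 computed directly from label vectors.

    Uses exact rational arithmetic (harmonic mean of precision and
    recall as a Fraction), so its correctly-rounded float must agree
    bit-for-bit with any faithful floating-point implementation.
    """
    from fractions import Fraction

    out = np.zeros(n_classes)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for c in range(1, n_classes + 1):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        if tp + fp == 0 or tp + fn == 0:
            out[c - 1] = 0.0
            continue
        p = Fraction(tp, tp + fp)
        r = Fraction(tp, tp + fn)
        out[c - 1] = 0.0 if p + r == 0 else float(2 * p * r / (p + r))
    return out


def gaussian_classes(rng, d, n, sep):
    """Two spherical Gaussian classes separated by Mahalanobis distance sep."""
    X0 = rng.normal(0.0, 1.0, size=(n, d))
    X1 = rng.normal(0.0, 1.0, size=(n, d))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    y = np.repeat([1, 2], n)
    return X, y


class TestBinaryLDA:
    def test_identical_classes_decide_by_prior(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 3))
        y = np.array([1] * 100 + [2] * 200)  # class 2 has double the prior
        model = fit_binary_lda(X, y)
        pred = model.predict(rng.normal(size=(50, 3)))
        assert np.all(pred == 2)

    def test_zero_variance_column_fits_with_zero_weight(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=200), np.zeros(200)])
        X[100:, 0] += 3.0
        y = np.repeat([1, 2], 100)
        model = fit_binary_lda(X, y)
        assert model.w[1] == 0.0
        acc = np.mean(model.predict(X) == y)
        assert acc > 0.9

    @pytest.mark.parametrize("d_sep", [1.0, 2.0, 3.0])
    def test_accuracy_approaches_bayes_limit(self, d_sep):
        """Equal-covariance Gaussians: Bayes accuracy is Phi(d/2)."""
        rng = np.random.default_rng(int(d_sep * 10))
        X, y = gaussian_classes(rng, 5, 2000, d_sep)
        model = fit_binary_lda(X, y)
        Xt, yt = gaussian_classes(rng, 5, 2000, d_sep)
        acc = np.mean(model.predict(Xt) == yt)
        assert abs(acc - norm.cdf(d_sep / 2.0)) < 0.02

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            fit_binary_lda(np.zeros((5, 2)), np.ones(5))


class TestEcoc:
    @staticmethod
    def clusters(rng, k=8, n=30, spread=0.05):
        centers = rng.normal(0.0, 5.0, size=(k, 4))
        X = np.vstack([centers[c] + rng.normal(0.0, spread, size=(n, 4)) for c in range(k)])
        y = np.repeat(np.arange(1, k + 1), n)
        return X, y, centers

    def test_28_learners_for_8_classes(self):
        rng = np.random.default_rng(0)
        X, y, _ = self.clusters(rng)
        model = fit_ecoc(X, y)
        assert len(model.learners) == 28
        pairs = {l.classes for l in model.learners}
        assert len(pairs) == 28  # every unordered pair exactly once

    def test_two_classes_single_learner_matches_binary(self):
        rng = np.random.default_rng(2)
        X, y = gaussian_classes(rng, 3, 200, 2.0)
        ecoc = fit_ecoc(X, y)
        binary = fit_binary_lda(X, y)
        assert len(ecoc.learners) == 1
        Xt, _ = gaussian_classes(rng, 3, 100, 2.0)
        assert np.array_equal(predict_ecoc(ecoc, Xt), binary.predict(Xt))

    def test_separable_clusters_reproduce_training_labels(self):
        rng = np.random.default_rng(3)
        X, y, _ = self.clusters(rng)
        model = fit_ecoc(X, y)
        assert np.array_equal(predict_ecoc(model, X), y)

    def test_centroid_wins_all_seven_votes(self):
        rng = np.random.default_rng(4)
        X, y, centers = self.clusters(rng)
        model = fit_ecoc(X, y)
        x = centers[2][None, :]  # centroid of class 3
        wins = 0
        for learner in model.learners:
            if 3 in learner.classes:
                pred = learner.predict(x)[0]
                wins += pred == 3
        assert wins == 7
        assert predict_ecoc(model, x)[0] == 3

    def test_prediction_deterministic(self):
        rng = np.random.default_rng(5)
        X, y, _ = self.clusters(rng, spread=2.0)
        model = fit_ecoc(X, y)
        x = np.repeat(X[:1], 10, axis=0)
        assert len(set(predict_ecoc(model, x))) == 1

    def test_all_zero_feature_column_is_harmless(self):
        """Windows with a silent channel (all-zero counts) must fit and
        predict without error."""
        rng = np.random.default_rng(6)
        X, y, _ = self.clusters(rng)
        X = np.column_stack([X, np.zeros(len(X))])
        model = fit_ecoc(X, y)
        pred = predict_ecoc(model, X)
        assert np.array_equal(pred, y)


class TestPerClassF1:
    def test_perfect_diagonal(self):
        assert np.allclose(per_class_f1(np.eye(8) * 5), 1.0)

    def test_absent_class_scores_zero(self):
        cm = np.zeros((8, 8))
        cm[0, 0] = 10
        f1 = per_class_f1(cm)
        assert f1[0] == 1.0 and np.all(f1[1:] == 0.0)

    def test_two_class_hand_computation(self):
        cm = np.array([[8, 2], [4, 6]])
        f1 = per_class_f1(cm)
        p1, r1 = 8 / 12, 8 / 10
        assert f1[0] == pytest.approx(2 * p1 * r1 / (p1 + r1))

    @settings(derandomize=True, max_examples=120)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_scorer(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 200))
        y_true = rng.integers(1, 9, size=n)
        y_pred = rng.integers(1, 9, size=n)
        cm = confusion_matrix(y_true, y_pred)
        assert np.array_equal(per_class_f1(cm), brute_force_f1(y_true, y_pred))


class TestEvaluateWindow:
    def test_separable_features_reach_perfect_f1(self):
        rng = np.random.default_rng(0)
        y = np.repeat(np.arange(1, 9), 30)
        X = y[:, None] + rng.normal(0.0, 0.01, size=(len(y), 2))
        score = evaluate_window(X, y, np.random.default_rng(1))
        assert np.allclose(score.f1, 1.0)

    def test_label_independent_features_are_chance(self):
        rng = np.random.default_rng(1)
        y = np.repeat(np.arange(1, 9), 100)
        X = rng.normal(size=(len(y), 10))
        score = evaluate_window(X, y, np.random.default_rng(2))
        assert 0.09 < score.f1.mean() < 0.16

    def test_shuffle_mode_breaks_real_structure(self):
        rng = np.random.default_rng(2)
        y = np.repeat(np.arange(1, 9), 100)
        X = y[:, None] + rng.normal(0.0, 0.01, size=(len(y), 2))
        score = evaluate_window(X, y, np.random.default_rng(3), shuffle=True)
        assert 0.08 < score.f1.mean() < 0.17

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        y = np.repeat(np.arange(1, 9), 20)
        X = rng.normal(size=(len(y), 5))
        a = evaluate_window(X, y, np.random.default_rng(7))
        b = evaluate_window(X, y, np.random.default_rng(7))
        assert np.array_equal(a.f1, b.f1)
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_total_matches_test_trials(self):
        rng = np.random.default_rng(4)
        y = np.repeat(np.arange(1, 9), 20)
        X = rng.normal(size=(len(y), 5))
        score = evaluate_window(X, y, np.random.default_rng(8))
        assert score.confusion.sum() == score.n_test
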