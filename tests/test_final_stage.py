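"""Hinge solver, final one-vs-all stage, fusion, ablations, evaluation."""

import numpy as np
import pytest

from fgmi import ConfigError
from fgmi.confusion_bank import ConfusionBank
from fgmi.final_stage import (
    FusionWeights,
    ablation_no_mi,
    ablation_no_nir,
    decision_scores,
    fuse,
    hinge_loss,
    hinge_objective,
    mean_class_accuracy,
    per_class_accuracy,
    train_final,
)
from fgmi.hinge import fit_binary_hinge

from _oracles import check_solver_against_grid


class TestHingeLoss:
    @pytest.mark.parametrize("score,y,expected", [
        (0.5, 1, 0.5),
        (2.0, 1, 0.0),
        (-1.0, 1, 2.0),
        (-0.5, -1, 0.5),
    ])
    def test_values(self, score, y, expected):
        assert hinge_loss(score, y) == expected

    def test_invalid_label(self):
        with pytest.raises(ConfigError):
            hinge_loss(0.5, 0)


class TestHingeSolver:
    def test_objective_at_zero_weights_is_n(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(17, 3))
        y = np.where(rng.uniform(size=17) < 0.5, 1.0, -1.0)
        assert hinge_objective(np.zeros(3), X, y, alpha=1.0) == 17.0

    def test_huge_alpha_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(10, 2))
        y = np.where(np.arange(10) < 5, 1.0, -1.0)
        w, _ = fit_binary_hinge(X, y, alpha=1e9)
        assert np.linalg.norm(w) < 1e-3

    def test_matches_grid_search_on_random_toys(self):
        check_solver_against_grid(
            lambda X, y, a: fit_binary_hinge(X, y, alpha=a),
            np.random.default_rng(7),
        )

    def test_objective_trace_non_increasing_on_hard_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            X = rng.normal(size=(n, 4)) * rng.uniform(0.1, 10)
            y = np.where(rng.uniform(size=n) < 0.4, 1.0, -1.0)
            if len(np.unique(y)) < 2:
                continue
            _, trace = fit_binary_hinge(X, y, alpha=0.3)
            assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1, np.abs(trace[:-1])))

    def test_agrees_with_liblinear(self):
        """Independent cross-check: liblinear solves the same objective."""
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 4))
        w_true = np.array([1.0, -2.0, 0.5, 0.0])
        y = np.where(X @ w_true + 0.3 * rng.normal(size=60) > 0, 1.0, -1.0)
        alpha = 0.5
        w, _ = fit_binary_hinge(X, y, alpha=alpha)
        svc = LinearSVC(C=1 / (2 * alpha), loss="hinge", fit_intercept=False,
                        max_iter=200_000, tol=1e-10).fit(X, y)
        mine = hinge_objective(w, X, y, alpha)
        theirs = hinge_objective(svc.coef_.ravel(), X, y, alpha)
        assert mine <= theirs + 1e-4 * max(1, theirs)

    def test_invalid_inputs(self):
        X = np.ones((4, 2))
        with pytest.raises(ConfigError):
            fit_binary_hinge(X, np.array([1.0, 2.0, 1.0, -1.0]))
        with pytest.raises(ConfigError):
            fit_binary_hinge(X, np.ones(4), alpha=0.0)


class TestTrainFinal:
    def test_bias_column_is_appended(self):
        rng = np.random.default_rng(5)
        H = rng.normal(size=(20, 3))
        y = np.repeat([1, 2], 10)
        clf = train_final(H, y, alpha=0.5)
        assert clf.weights.shape == (2, 4)
        scores = decision_scores(H, clf)
        assert scores.shape == (20, 2)

    def test_no_positives_rejected(self):
        H = np.ones((4, 2))
        with pytest.raises(ConfigError):
            train_final(H, np.array([1, 1, 1, 3]), alpha=1.0)

    def test_non_positive_alpha_rejected(self):
        with pytest.raises(ConfigError):
            train_final(np.ones((4, 2)), np.array([1, 1, 2, 2]), alpha=-1.0)


class TestFusion:
    def test_single_model_is_identity(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(6, 4))
        fused = fuse([s])
        np.testing.assert_array_equal(fused.scores, s)
        np.testing.assert_array_equal(fused.predicted_labels,
                                      np.argmax(s, axis=1) + 1)

    def test_equal_weights_average(self):
        a = np.array([[0.2, 0.8]])
        b = np.array([[0.4, 0.6]])
        np.testing.assert_allclose(fuse([a, b]).scores, [[0.3, 0.7]])

    def test_duplicated_model_leaves_labels_unchanged(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(30, 5))
        base = fuse([s]).predicted_labels
        for m in (2, 3, 7):
            np.testing.assert_array_equal(fuse([s] * m).predicted_labels, base)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            fuse([np.ones((2, 3)), np.ones((2, 4))])

    def test_custom_weights_shape_checked(self):
        with pytest.raises(ConfigError):
            fuse([np.ones((2, 3))], FusionWeights(np.ones((2, 3))))


class TestAblations:
    def test_no_mi_is_equal_weight_fusion(self):
        rng = np.random.default_rng(4)
        scores = [rng.normal(size=(25, 6)) for _ in range(3)]
        np.testing.assert_array_equal(ablation_no_mi(scores),
                                      fuse(scores).predicted_labels)

    def test_no_mi_single_model(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(ablation_no_mi([s]),
                                      np.argmax(s, axis=1) + 1)

    def test_no_mi_mean_decides(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 0.5]])
        assert ablation_no_mi([a, b]).tolist() == [1]  # mean (0.5, 0.25)

    def test_no_mi_empty_rejected(self):
        with pytest.raises(ConfigError):
            ablation_no_mi([])

    @staticmethod
    def _constant_bank(winner_bias, orderings):
        """Bank whose classifiers output fixed biases for any input."""
        c, kp1 = orderings.shape
        w = np.zeros((c, kp1, 3))
        w[:, :, -1] = winner_bias
        return ConfusionBank(weights=w, orderings=orderings)

    def test_no_nir_majority_vote(self):
        # subsets (c=1..3) emit winners 2, 2, 3 -> majority 2
        orderings = np.array([[1, 2], [2, 3], [3, 1]])
        bias = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        bank = self._constant_bank(bias, orderings)
        pred = ablation_no_nir([bank], [np.zeros((2, 2))])
        assert pred.tolist() == [2, 2]

    def test_no_nir_unanimous(self):
        orderings = np.array([[1, 3], [2, 3], [3, 1]])
        bias = np.array([[0.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        bank = self._constant_bank(bias, orderings)
        assert ablation_no_nir([bank], [np.zeros((1, 2))]).tolist() == [3]

    def test_no_nir_tie_breaks_low(self):
        # C=4: winners 1, 1, 2, 2 -> tie between 1 and 2 -> class 1
        orderings = np.array([[1, 2], [2, 1], [3, 2], [4, 2]])
        bias = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        bank = self._constant_bank(bias, orderings)
        assert ablation_no_nir([bank], [np.zeros((1, 2))]).tolist() == [1]

    def test_no_nir_requires_banks(self):
        with pytest.raises(ConfigError):
            ablation_no_nir([], [])


class TestMeanClassAccuracy:
    def test_perfect(self):
        y = np.array([1, 2, 2, 3])
        assert mean_class_accuracy(y, y) == 1.0

    def test_unweighted_over_classes(self):
        true = np.array([1, 1, 1, 2])
        pred = np.array([1, 1, 1, 1])  # class 1 all right, class 2 all wrong
        assert mean_class_accuracy(pred, true) == 0.5
        assert np.mean(pred == true) == 0.75  # pooled accuracy differs

    def test_per_class_values(self):
        true = np.array([1, 1, 2, 2])
        pred = np.array([1, 2, 2, 2])
        np.testing.assert_allclose(per_class_accuracy(pred, true), [0.5, 1.0])

    def test_empty_class_rejected(self):
        with pytest.raises(ConfigError):
            mean_class_accuracy(np.array([1, 1]), np.array([1, 1]), n_classes=2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            mean_class_accuracy(np.array([1]), np.array([1, 2]))
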