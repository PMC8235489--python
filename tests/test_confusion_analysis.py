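"""Confusion profiles, top-K selection and subset construction,
checked against hand enumerations and a brute-force counting oracle."""

import collections

import numpy as np
import pytest

from fgmi import BaseModelHandle, ConfigError
from fgmi.confusion_analysis import (
    ScoreMatrix,
    build_subset,
    confusion_profile,
    predict_with_base,
    select_top_k,
)


def one_hot_scores(predictions, n_classes):
    """Score matrix whose argmax reproduces the given 1-based predictions."""
    s = np.zeros((len(predictions), n_classes))
    s[np.arange(len(predictions)), np.asarray(predictions) - 1] = 1.0
    return ScoreMatrix(scores=s)


class TestPrediction:
    def test_argmax(self):
        sm = ScoreMatrix(scores=np.array([[0.1, 0.7, 0.2]]))
        assert sm.predicted_labels.tolist() == [2]

    def test_tie_breaks_to_lowest_class(self):
        sm = ScoreMatrix(scores=np.array([[0.5, 0.5, 0.0]]))
        assert sm.predicted_labels.tolist() == [1]

    def test_empty_input_is_vacuous(self):
        handle = BaseModelHandle(score_fn=lambda X: np.zeros((X.shape[0], 3)))
        sm = predict_with_base(handle, np.zeros((0, 4)))
        assert sm.scores.shape == (0, 3)
        assert sm.predicted_labels.shape == (0,)

    def test_misshapen_scores_rejected(self):
        handle = BaseModelHandle(score_fn=lambda X: np.zeros(X.shape[0]))
        with pytest.raises(ConfigError):
            predict_with_base(handle, np.zeros((2, 4)))


class TestConfusionProfile:
    def test_hand_enumeration(self):
        # 4 class-1 images predicted 1,2,2,3
        prof = confusion_profile(one_hot_scores([1, 2, 2, 3], 3),
                                 np.array([1, 1, 1, 1]), c=1)
        np.testing.assert_allclose(prof.proportions, [0.25, 0.5, 0.25])
        assert prof.sorted_order.tolist() == [2, 1, 3]

    def test_all_correct_is_degenerate(self):
        prof = confusion_profile(one_hot_scores([2, 2, 2], 3),
                                 np.array([2, 2, 2]), c=2)
        np.testing.assert_allclose(prof.proportions, [0.0, 1.0, 0.0])

    def test_tie_break_in_sorted_order(self):
        prof = confusion_profile(one_hot_scores([2, 2, 3, 3], 3),
                                 np.array([1, 1, 1, 1]), c=1)
        np.testing.assert_allclose(prof.proportions, [0.0, 0.5, 0.5])
        assert prof.sorted_order.tolist() == [2, 3, 1]

    def test_absent_class_rejected(self):
        with pytest.raises(ConfigError):
            confusion_profile(one_hot_scores([1, 1], 3), np.array([1, 1]), c=2)


class TestSelectTopK:
    @pytest.fixture()
    def profile(self):
        return confusion_profile(one_hot_scores([1, 2, 2, 3], 3),
                                 np.array([1, 1, 1, 1]), c=1)

    def test_self_excluded(self, profile):
        assert select_top_k(profile, 1) == [2]

    def test_k_two(self, profile):
        assert select_top_k(profile, 2) == [2, 3]

    def test_k_equals_c_minus_one_is_rank_order(self):
        prof = confusion_profile(one_hot_scores([1, 3, 3, 4], 4),
                                 np.array([1] * 4), c=1)
        assert select_top_k(prof, 3) == [3, 4, 2]

    @pytest.mark.parametrize("bad_k", [0, 3, 5])
    def test_invalid_k(self, profile, bad_k):
        with pytest.raises(ConfigError):
            select_top_k(profile, bad_k)

    def test_zero_confusion_fallback_uses_mean_scores(self):
        # class 1 never misclassified; slots filled by mean score rank
        scores = np.array([[5.0, 1.0, 3.0], [5.0, 1.0, 3.0]])
        prof = confusion_profile(ScoreMatrix(scores=scores),
                                 np.array([1, 1]), c=1)
        assert select_top_k(prof, 2) == [3, 2]


class TestBuildSubset:
    def test_hand_filter(self):
        spec = build_subset(np.array([1, 2, 2, 3]), c=1, selected=[2])
        assert spec.member_indices.tolist() == [0, 1, 2]
        assert spec.subset_size == 3
        assert spec.member_classes == (1, 2)

    def test_all_classes_covers_everything(self):
        y = np.array([1, 2, 3, 1])
        spec = build_subset(y, c=2, selected=[1, 3])
        assert spec.member_indices.tolist() == [0, 1, 2, 3]

    def test_self_in_selected_rejected(self):
        with pytest.raises(ConfigError):
            build_subset(np.array([1, 2]), c=1, selected=[1])

    def test_duplicate_selected_rejected(self):
        with pytest.raises(ConfigError):
            build_subset(np.array([1, 2, 3]), c=1, selected=[2, 2])


def brute_force_profile_and_topk(predictions, y, c, K):
    """Independent counting-and-sorting oracle."""
    rows = [p for p, t in zip(predictions, y) if t == c]
    counts = collections.Counter(rows)
    n_classes = int(max(y.max(), max(predictions)))
    props = [counts.get(j, 0) / len(rows) for j in range(1, n_classes + 1)]
    order = sorted(range(1, n_classes + 1), key=lambda j: (-props[j - 1], j))
    others = [j for j in range(1, n_classes + 1) if j != c]
    ranked = sorted(others, key=lambda j: (-props[j - 1], j))
    topk = [j for j in ranked if props[j - 1] > 0][:K]
    return props, order, topk


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_classes = int(rng.integers(2, 7))
            n = int(rng.integers(n_classes, 51))
            y = np.concatenate([np.arange(1, n_classes + 1),
                                rng.integers(1, n_classes + 1, n - n_classes)])
            predictions = rng.integers(1, n_classes + 1, n)
            sm = one_hot_scores(predictions, n_classes)
            c = int(rng.integers(1, n_classes + 1))
            K = int(rng.integers(1, n_classes))
            prof = confusion_profile(sm, y, c)
            props, order, topk = brute_force_profile_and_topk(predictions, y, c, K)
            np.testing.assert_array_equal(prof.proportions, props)
            assert prof.sorted_order.tolist() == order
            assert prof.proportions.sum() == pytest.approx(1.0, abs=1e-12)
            sorted_props = prof.proportions[prof.sorted_order - 1]
            assert np.all(np.diff(sorted_props) <= 0)
            got = select_top_k(prof, K)
            # the oracle only ranks nonzero-mass classes; the implementation
            # fills remaining slots deterministically
            assert got[: len(topk)] == topk
            assert len(got) == K and len(set(got)) == K and c not in got

    def test_determinism(self):
        rng = np.random.default_rng(0)
        y = rng.integers(1, 5, 40)
        y[:4] = [1, 2, 3, 4]
        sm = one_hot_scores(rng.integers(1, 5, 40), 4)
        a = select_top_k(confusion_profile(sm, y, 2), 2)
        b = select_top_k(confusion_profile(sm, y, 2), 2)
        assert a == b
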