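"""Mid-level features: expression scores, label transitions, motion SD."""

import numpy as np
import pytest

from affectfar.features import (
    ExpressionModel,
    combined_feature,
    expression_feature,
    expression_scores,
    label_feature,
    motion_feature,
    train_expression_model,
)
from affectfar.vocab import EXPRESSION_CLASSES

from conftest import expr_index, frames_for_labels, make_series


@pytest.fixture
def separable_two_class():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.3, (20, 6)) + np.array([5, 0, 0, 0, 0, 0])
    b = rng.normal(0.0, 0.3, (20, 6)) + np.array([0, 5, 0, 0, 0, 0])
    X = np.vstack([a, b])
    y = np.array(["anger"] * 20 + ["happiness"] * 20)
    return X, y


class TestTrainExpressionModel:
    def test_separable_classes_fit_perfectly(self, separable_two_class):
        X, y = separable_two_class
        model = train_expression_model(X, y)
        pred = [EXPRESSION_CLASSES[int(np.argmax(expression_scores(x, model)))] for x in X]
        assert pred == list(y)
        # absent classes can never win: constant most-negative scorers
        absent = set(EXPRESSION_CLASSES) - {"anger", "happiness"}
        for cls in absent:
            assert model.biases[expr_index(cls)] < -1e5
            assert not np.any(model.weights[expr_index(cls)])

    def test_deterministic(self, separable_two_class):
        X, y = separable_two_class
        m1 = train_expression_model(X, y, seed=3)
        m2 = train_expression_model(X, y, seed=3)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.biases, m2.biases)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            train_expression_model(np.ones((5, 3)), np.array(["anger"] * 5))
        with pytest.raises(ValueError):
            train_expression_model([[1, 2], [1, 2, 3]], np.array(["anger", "fear"]))


class TestExpressionScores:
    def test_zero_model_ties_resolve_to_norm(self):
        model = ExpressionModel(np.zeros((7, 4)), np.zeros(7), np.zeros(4), np.ones(4))
        scores = expression_scores(np.ones(4), model)
        assert np.all(scores == 0.0)
        assert EXPRESSION_CLASSES[int(np.argmax(scores))] == "norm"

    def test_seven_finite_scores_and_length_check(self):
        model = ExpressionModel(np.ones((7, 4)), np.zeros(7), np.zeros(4), np.ones(4))
        scores = expression_scores([1, 2, 3, 4], model)
        assert scores.shape == (7,) and np.all(np.isfinite(scores))
        with pytest.raises(ValueError, match="length-4"):
            expression_scores([1, 2, 3], model)


class TestExpressionFeature:
    def test_mean_aggregation(self, indicator_model):
        X = frames_for_labels([2, 2, 2])
        feat = expression_feature(make_series(X, (2, 4), 8), indicator_model)
        single = expression_scores(X[:, 0], indicator_model)
        assert np.allclose(feat.values, single)
        X2 = np.column_stack([X[:, 0], 3 * X[:, 0]])
        feat2 = expression_feature(make_series(X2, (2, 4), 8), indicator_model)
        s1 = expression_scores(X2[:, 0], indicator_model)
        s2 = expression_scores(X2[:, 1], indicator_model)
        assert np.allclose(feat2.values, (s1 + s2) / 2)

    def test_matches_bruteforce_frame_loop(self, expression_model):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 255, (64, 100))
        series = make_series(X, (8, 8), 48)
        feat = expression_feature(series, expression_model)
        brute = np.mean([expression_scores(X[:, n], expression_model) for n in range(100)],
                        axis=0)
        assert np.allclose(feat.values, brute, atol=1e-9)

    def test_invariant_to_frame_permutation(self, expression_model):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 255, (64, 30))
        perm = rng.permutation(30)
        f1 = expression_feature(make_series(X, (8, 8), 48), expression_model)
        f2 = expression_feature(make_series(X[:, perm], (8, 8), 48), expression_model)
        assert np.allclose(f1.values, f2.values, atol=1e-9)


class TestLabelFeature:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([0, 0, 0, 0], 0),
            ([0, 0, 1, 1, 0], 2),  # A,A,B,B,A
            ([0, 1] * 10, 19),  # strict alternation over N frames: N-1
        ],
    )
    def test_transition_counts(self, indicator_model, seq, expected):
        series = make_series(frames_for_labels(seq), (2, 4), 8)
        assert label_feature(series, indicator_model).values[0] == expected

    def test_sensitive_to_frame_order(self, indicator_model):
        alternating = make_series(frames_for_labels([0, 1, 0, 1]), (2, 4), 8)
        sorted_ = make_series(frames_for_labels([0, 0, 1, 1]), (2, 4), 8)
        assert label_feature(alternating, indicator_model).values[0] == 3
        assert label_feature(sorted_, indicator_model).values[0] == 1


class TestMotionFeature:
    def test_two_point_sd(self):
        series = make_series(np.array([[0.0, 10.0]]), (1, 1), 4)
        assert motion_feature(series).values[0] == pytest.approx(5.0, abs=1e-12)

    def test_ramp_sd(self):
        series = make_series(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]), (1, 1), 4)
        assert motion_feature(series).values[0] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_constant_video_zero(self):
        series = make_series(np.full((4, 6), 7.0), (2, 2), 4)
        assert motion_feature(series).values[0] == 0.0

    def test_empty_cell_subset_rejected(self):
        series = make_series(np.ones((4, 3)), (2, 2), 4)
        with pytest.raises(ValueError, match="non-empty"):
            motion_feature(series, frozenset())

    def test_scales_linearly_with_intensity(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 100, (4, 20))
        s1 = make_series(X, (2, 2), 4)
        s2 = make_series(3.0 * X, (2, 2), 4)
        assert motion_feature(s2).values[0] == pytest.approx(
            3.0 * motion_feature(s1).values[0], rel=1e-12)

    def test_composite_group_equals_explicit_union(self):
        from affectfar.facegrid import partition_faceparts

        rng = np.random.default_rng(10)
        X = rng.uniform(0, 255, (64, 30))
        series = make_series(X, (8, 8), 48)
        part = partition_faceparts((8, 8))
        union = part.parts["left_eye"] | part.parts["right_eye"]
        a = motion_feature(series, part.cells("eyes")).values[0]
        b = motion_feature(series, union).values[0]
        assert a == pytest.approx(b, abs=1e-12)


class TestCombinedFeature:
    def test_motion_label_concatenation(self):
        mot = motion_feature(make_series(np.array([[0.0, 1.0]]), (1, 1), 4, "p1"))
        lab = label_feature(
            make_series(frames_for_labels([0, 1, 1, 0], 8), (2, 4), 8, "p1"),
            ExpressionModel(np.eye(8)[:7], np.zeros(7), np.zeros(8), np.ones(8)),
        )
        feat = combined_feature("motion_label", mot, lab)
        assert feat.values.shape == (2,)
        assert feat.values[0] == mot.values[0] and feat.values[1] == lab.values[0]

    def test_motion_expression_length_eight(self, indicator_model):
        X = frames_for_labels([4, 4])
        series = make_series(X, (2, 4), 8, "p1")
        mot = motion_feature(series)
        expr = expression_feature(series, indicator_model)
        feat = combined_feature("motion_expression", mot, expr)
        assert feat.values.shape == (8,)
        assert feat.values[0] == mot.values[0]

    def test_provenance_mismatch_rejected(self, indicator_model):
        s1 = make_series(frames_for_labels([0, 1]), (2, 4), 8, "p1")
        s2 = make_series(frames_for_labels([0, 1]), (2, 4), 8, "p2")
        with pytest.raises(ValueError, match="different patients"):
            combined_feature("motion_label", motion_feature(s1),
                             label_feature(s2, indicator_model))

    def test_kind_mismatch_rejected(self, indicator_model):
        s = make_series(frames_for_labels([0, 1]), (2, 4), 8, "p1")
        with pytest.raises(ValueError):
            combined_feature("motion_label", motion_feature(s),
                             expression_feature(s, indicator_model))
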