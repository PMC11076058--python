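"""Metric correctness against independent scalar-loop oracles.

The vectorized implementations of the rounding function, 4-class accuracies,
MAE and presence-F1 are checked cell by cell with naive Python loops and,
for F1, against scikit-learn.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import f1_score

from emossl.metrics import (
    evaluate,
    f1_per_emotion,
    four_class_accuracy,
    four_class_accuracy_per_emotion,
    mae,
    round_intensity,
)


# ---------------------------------------------------------------------------
# independent scalar oracles


def oracle_round(x: float) -> int:
    import math

    fl = math.floor(x)
    return fl if (x - fl) < 0.5 else fl + 1


def oracle_clamp_round(x: float) -> int:
    return oracle_round(min(max(x, 0.0), 3.0))


def oracle_overall_accuracy(pred, true) -> float:
    n, m = pred.shape
    hits = 0
    for k in range(n):
        for i in range(m):
            if oracle_clamp_round(pred[k][i]) == oracle_clamp_round(true[k][i]):
                hits += 1
    return hits / (m * n)


def oracle_column_accuracy(pred, true, j) -> float:
    n = pred.shape[0]
    hits = sum(
        1
        for k in range(n)
        if oracle_clamp_round(pred[k][j]) == oracle_clamp_round(true[k][j])
    )
    return hits / n


def oracle_mae(pred, true, j=None) -> float:
    n, m = pred.shape
    if j is None:
        return sum(abs(pred[k][i] - true[k][i]) for k in range(n) for i in range(m)) / (n * m)
    return sum(abs(pred[k][j] - true[k][j]) for k in range(n)) / n


def oracle_f1(pred, true, j) -> float:
    tp = fp = fn = 0
    for k in range(pred.shape[0]):
        p = oracle_clamp_round(pred[k][j]) >= 1
        t = oracle_clamp_round(true[k][j]) >= 1
        tp += p and t
        fp += p and not t
        fn += (not p) and t
    if tp == fp == fn == 0:
        return 1.0
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,expected",
    [(1.4, 1), (1.5, 2), (0.0, 0), (2.5, 3), (0.49999, 0), (2.9, 3)],
)
def test_round_intensity_values(x, expected):
    assert round_intensity(x) == expected


def test_round_intensity_rejects_non_finite():
    with pytest.raises(ValueError):
        round_intensity(float("nan"))


def test_identity_predictions_score_perfectly(rng):
    true = rng.uniform(0, 3, size=(12, 6))
    assert four_class_accuracy(true, true) == 1.0
    assert mae(true, true) == 0.0
    for j in range(6):
        assert four_class_accuracy_per_emotion(true, true, j) == 1.0


def test_half_agreement_accuracy():
    true = np.array([[0.0] * 6, [1.0] * 6])
    pred = np.zeros((2, 6))
    assert four_class_accuracy(pred, true) == 0.5


def test_offset_below_half_rounds_back(rng):
    true = rng.integers(0, 4, size=(10, 6)).astype(float)
    pred = true + 0.4
    assert four_class_accuracy(pred, true) == 1.0


def test_single_cell_per_emotion_accuracy():
    true = np.zeros((1, 6))
    true[0, 2] = 3.0
    pred = np.zeros((1, 6))
    pred[0, 2] = 2.6
    assert four_class_accuracy_per_emotion(pred, true, 2) == 1.0


def test_mae_constant_offset_and_signs(rng):
    true = rng.uniform(0, 3, size=(8, 6))
    assert mae(true + 0.25, true) == pytest.approx(0.25)
    signs = rng.choice([-0.1, 0.1], size=(8, 6))
    assert mae(true + signs, true) == pytest.approx(0.1)


def test_mae_is_not_clamped():
    true = np.zeros((1, 6))
    pred = np.full((1, 6), 5.0)
    assert mae(pred, true) == pytest.approx(5.0)
    # but accuracy clamps 5.0 -> class 3, disagreeing with class 0
    assert four_class_accuracy(pred, true) == 0.0


def test_f1_hand_computed_case():
    # TP=2, FP=1, FN=1 over emotion column 0 -> F1 = 2/3
    true = np.zeros((4, 6))
    pred = np.zeros((4, 6))
    true[[0, 1, 2], 0] = 2.0
    pred[[0, 1, 3], 0] = 2.0
    assert f1_per_emotion(pred, true, 0) == pytest.approx(2 / 3)


def test_f1_degenerate_conventions():
    true = np.zeros((5, 6))
    pred = np.zeros((5, 6))
    assert f1_per_emotion(pred, true, 0) == 1.0  # agreement on total absence
    true[0, 0] = 2.0
    assert f1_per_emotion(pred, true, 0) == 0.0  # recall 0


def test_f1_matches_sklearn(rng):
    for _ in range(20):
        true = rng.uniform(0, 3, size=(30, 6))
        pred = rng.uniform(-0.5, 3.5, size=(30, 6))
        for j in range(6):
            t = np.clip(np.floor(true[:, j] + 0.5), 0, 3) >= 1
            p = np.clip(np.floor(np.clip(pred[:, j], 0, 3) + 0.5), 0, 3) >= 1
            if t.any() or p.any():
                expected = f1_score(t, p, zero_division=0.0)
                assert f1_per_emotion(pred, true, j) == pytest.approx(expected)


def test_vectorized_matches_scalar_oracles(rng):
    """100 random matrices, every metric, to machine precision."""
    for _ in range(100):
        n = int(rng.integers(1, 51))
        true = rng.uniform(0, 3, size=(n, 6))
        pred = rng.uniform(-1, 4, size=(n, 6))
        assert four_class_accuracy(pred, true) == pytest.approx(
            oracle_overall_accuracy(pred, true), abs=1e-12
        )
        assert mae(pred, true) == pytest.approx(oracle_mae(pred, true), abs=1e-12)
        for j in range(6):
            assert four_class_accuracy_per_emotion(pred, true, j) == pytest.approx(
                oracle_column_accuracy(pred, true, j), abs=1e-12
            )
            assert mae(pred, true, j) == pytest.approx(
                oracle_mae(pred, true, j), abs=1e-12
            )
            assert f1_per_emotion(pred, true, j) == pytest.approx(
                oracle_f1(pred, true, j), abs=1e-12
            )


def test_per_emotion_mean_equals_overall(rng):
    """With equal n per column the 6 per-emotion accuracies average to the
    overall accuracy (algebraic identity of the two definitions)."""
    true = rng.uniform(0, 3, size=(25, 6))
    pred = rng.uniform(0, 3, size=(25, 6))
    per = [four_class_accuracy_per_emotion(pred, true, j) for j in range(6)]
    assert np.mean(per) == pytest.approx(four_class_accuracy(pred, true), abs=1e-12)


def test_permutation_consistency(rng):
    perm = rng.permutation(6)
    true = rng.uniform(0, 3, size=(15, 6))
    pred = rng.uniform(-1, 4, size=(15, 6))
    for j in range(6):
        assert four_class_accuracy_per_emotion(
            pred[:, perm], true[:, perm], j
        ) == pytest.approx(four_class_accuracy_per_emotion(pred, true, perm[j]))
        assert f1_per_emotion(pred[:, perm], true[:, perm], j) == pytest.approx(
            f1_per_emotion(pred, true, perm[j])
        )


def test_shape_and_index_errors(rng):
    true = rng.uniform(0, 3, size=(5, 6))
    with pytest.raises(ValueError):
        four_class_accuracy(true[:4], true)
    with pytest.raises(ValueError):
        mae(true[:, :5], true[:, :5])
    with pytest.raises(ValueError):
        four_class_accuracy_per_emotion(true, true, 6)
    with pytest.raises(ValueError):
        f1_per_emotion(true, true, -1)


@settings(derandomize=True, max_examples=50)
@given(
    pred=arrays(np.float64, (7, 6), elements=st.floats(-2, 5)),
    true=arrays(np.float64, (7, 6), elements=st.floats(0, 3)),
)
def test_metric_invariants_hold_for_any_scores(pred, true):
    """Accuracy and F1 stay in [0,1], MAE >= 0, and clamping inside the
    accuracy never affects MAE, for arbitrary finite score matrices."""
    acc = four_class_accuracy(pred, true)
    assert 0.0 <= acc <= 1.0
    assert mae(pred, true) >= 0.0
    clamped = np.clip(pred, 0, 3)
    assert four_class_accuracy(clamped, true) == acc
    for j in range(6):
        assert 0.0 <= f1_per_emotion(pred, true, j) <= 1.0


def test_evaluate_report_bounds(rng):
    true = rng.uniform(0, 3, size=(40, 6))
    pred = rng.uniform(-1, 4, size=(40, 6))
    rep = evaluate(pred, true)
    assert 0.0 <= rep.overall_4class_accuracy <= 1.0
    assert np.all(rep.per_emotion_4class_accuracy >= 0)
    assert np.all(rep.per_emotion_4class_accuracy <= 1)
    assert rep.overall_mae >= 0
    assert np.all((rep.per_emotion_f1 >= 0) & (rep.per_emotion_f1 <= 1))
    d = rep.as_dict()
    assert len(d) == 2 + 18
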