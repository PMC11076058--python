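"""Evaluation metrics for emotion-intensity regression.

True intensities are floats in [0, 3]; predictions are unrestricted reals.
Because direct accuracy on floats is ill-defined, the 4-class accuracy first
rounds every value to the nearest integer class in {0, 1, 2, 3} — ties
(fractional part exactly 0.5) round *up* — and then scores exact class
agreement, either over all six emotion columns (overall) or over a single
column (per emotion).  Predictions are clamped to [0, 3] before rounding so
no fifth class can appear; MAE is the standard mean absolute difference on
the raw floats and is never clamped.

The per-emotion F1 treats an emotion as *present* when its (clamped,
rounded) intensity is >= 1 and scores binary presence agreement.  The
alternative binarization "raw value > 0" is available via ``presence``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import EMOTIONS

N_EMOTIONS = 6
CLASS_MIN, CLASS_MAX = 0.0, 3.0


@dataclass
class MetricReport:
    """All evaluation metrics for one (predictions, truth) pair."""

    overall_4class_accuracy: float
    per_emotion_4class_accuracy: np.ndarray
    overall_mae: float
    per_emotion_mae: np.ndarray
    per_emotion_f1: np.ndarray

    def as_dict(self) -> dict[str, float]:
        d = {
            "overall_4class_accuracy": self.overall_4class_accuracy,
            "overall_mae": self.overall_mae,
        }
        for j, name in enumerate(EMOTIONS):
            d[f"accuracy_{name}"] = float(self.per_emotion_4class_accuracy[j])
            d[f"mae_{name}"] = float(self.per_emotion_mae[j])
            d[f"f1_{name}"] = float(self.per_emotion_f1[j])
        return d


def _check_pair(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    if pred.ndim != 2 or pred.shape[1] != N_EMOTIONS:
        raise ValueError(f"expected (n x {N_EMOTIONS}) score matrices, got {pred.shape}")
    if pred.shape[0] < 1:
        raise ValueError("need at least one sample")
    return pred, true


def round_intensity(x):
    """Round to the nearest integer class; fractional part >= 0.5 rounds up.

    Accepts a scalar or array; non-finite input is rejected.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any(~np.isfinite(arr)):
        raise ValueError("cannot round non-finite intensities")
    rounded = np.floor(arr + 0.5)
    if np.isscalar(x) or arr.ndim == 0:
        return int(rounded)
    return rounded.astype(int)


def _to_classes(values: np.ndarray) -> np.ndarray:
    """Clamp to [0, 3] then round — the 4-class discretization."""
    return round_intensity(np.clip(values, CLASS_MIN, CLASS_MAX))


def four_class_accuracy(pred, true) -> float:
    """Fraction of the 6n cells whose rounded classes agree."""
    pred, true = _check_pair(pred, true)
    return float(np.mean(_to_classes(pred) == _to_classes(true)))


def four_class_accuracy_per_emotion(pred, true, j: int) -> float:
    """4-class accuracy restricted to emotion column ``j`` (0-based)."""
    pred, true = _check_pair(pred, true)
    if not 0 <= j < N_EMOTIONS:
        raise ValueError(f"emotion index {j} out of range [0, {N_EMOTIONS})")
    return float(np.mean(_to_classes(pred[:, j]) == _to_classes(true[:, j])))


def mae(pred, true, j: int | None = None) -> float:
    """Mean absolute error on the raw floats, overall or for one emotion."""
    pred, true = _check_pair(pred, true)
    if j is None:
        return float(np.mean(np.abs(pred - true)))
    if not 0 <= j < N_EMOTIONS:
        raise ValueError(f"emotion index {j} out of range [0, {N_EMOTIONS})")
    return float(np.mean(np.abs(pred[:, j] - true[:, j])))


def f1_per_emotion(pred, true, j: int, presence: str = "rounded") -> float:
    """Binary F1 on emotion presence for column ``j``.

    presence='rounded': present iff the clamped, rounded intensity >= 1
    (the default); presence='positive': present iff the raw value > 0.
    Conventions for degenerate cases: if there are no true and no predicted
    positives the score is 1.0 (perfect agreement on absence); otherwise if
    precision + recall = 0 the score is 0.0.
    """
    pred, true = _check_pair(pred, true)
    if not 0 <= j < N_EMOTIONS:
        raise ValueError(f"emotion index {j} out of range [0, {N_EMOTIONS})")
    if presence == "rounded":
        p = _to_classes(pred[:, j]) >= 1
        t = _to_classes(true[:, j]) >= 1
    elif presence == "positive":
        p = pred[:, j] > 0
        t = true[:, j] > 0
    else:
        raise ValueError(f"unknown presence convention {presence!r}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2.0 * precision * recall / (precision + recall))


def evaluate(pred, true) -> MetricReport:
    """Compute the full metric surface for a (n x 6) prediction matrix."""
    pred, true = _check_pair(pred, true)
    return MetricReport(
        overall_4class_accuracy=four_class_accuracy(pred, true),
        per_emotion_4class_accuracy=np.array(
            [four_class_accuracy_per_emotion(pred, true, j) for j in range(N_EMOTIONS)]
        ),
        overall_mae=mae(pred, true),
        per_emotion_mae=np.array([mae(pred, true, j) for j in range(N_EMOTIONS)]),
        per_emotion_f1=np.array(
            [f1_per_emotion(pred, true, j) for j in range(N_EMOTIONS)]
        ),
    )
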