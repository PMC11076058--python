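"""Core dataset types, on-disk format, standardization and splitting.

A dataset on disk is a directory::

    <root>/
      clips/<clip_id>.csv   # T rows x 74 numeric columns, header row
      labels.csv            # clip_id, happiness, sadness, anger,
                            # surprise, disgust, fear

Clips are variable-length sequences of 74 engineered acoustic descriptors
per timestep (the COVAREP-style feature space); labels are Ekman emotion
intensities on a 0-3 scale.  Clips without a row in ``labels.csv`` are
unlabeled and usable only for self-supervised pre-training.

Standardization is per-feature z-scoring fit on the training split only and
applied to both splits; this is what puts the data in a bounded range that
the mask sentinel (-30) can never collide with.  Non-finite raw entries map
to 0 after standardization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FEATURES = 74
EMOTIONS = ("happiness", "sadness", "anger", "surprise", "disgust", "fear")

TRAIN, VALIDATION = "train", "validation"


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset violates the format contract."""


@dataclass
class FeatureSequence:
    """One clip's (T x 74) feature matrix."""

    clip_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DatasetFormatError(
                f"clip {self.clip_id!r}: expected a 2-D matrix, got ndim={self.values.ndim}"
            )

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]


@dataclass
class EmotionLabel:
    """Six emotion intensities in [0, 3], fixed order (happiness, sadness,
    anger, surprise, disgust, fear)."""

    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.shape != (6,):
            raise ValueError("an emotion label has exactly 6 intensities")
        if np.any(~np.isfinite(self.intensities)):
            raise ValueError("emotion intensities must be finite")
        if np.any(self.intensities < 0) or np.any(self.intensities > 3):
            raise ValueError("emotion intensities must lie in [0, 3]")


@dataclass
class Dataset:
    clips: list[FeatureSequence]
    labels: dict[str, EmotionLabel] = field(default_factory=dict)
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.clip_id for c in self.clips]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clip_ids in dataset")
        missing = set(self.labels) - set(ids)
        if missing:
            raise ValueError(f"labels for unknown clips: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.clips)

    def clip(self, clip_id: str) -> FeatureSequence:
        for c in self.clips:
            if c.clip_id == clip_id:
                return c
        raise KeyError(clip_id)

    def subset(self, tag: str) -> list[FeatureSequence]:
        """Clips assigned to split ``tag`` (lexicographic clip_id order)."""
        return [c for c in self.clips if self.split.get(c.clip_id) == tag]

    def labeled(self, tag: str | None = None) -> list[tuple[FeatureSequence, EmotionLabel]]:
        clips = self.clips if tag is None else self.subset(tag)
        return [(c, self.labels[c.clip_id]) for c in clips if c.clip_id in self.labels]


@dataclass
class StandardizationStats:
    """Per-feature mean/SD fit on training clips.  Zero-variance features are
    flagged and their SD set to 1 so they standardize to 0."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray | None = None

    def __post_init__(self):
        if self.zero_variance is None:
            self.zero_variance = np.zeros_like(np.asarray(self.sd), dtype=bool)

    def transform(self, values: np.ndarray) -> np.ndarray:
        z = (values - self.mean) / self.sd
        z[~np.isfinite(z)] = 0.0
        if self.zero_variance.any():
            z[:, self.zero_variance] = 0.0
        return z

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


# ---------------------------------------------------------------------------
# I/O


def load_dataset(path: str | os.PathLike) -> Dataset:
    """Read a dataset directory; clips sorted lexicographically by clip_id.

    Raises :class:`DatasetFormatError` naming the offending file on a wrong
    feature count, non-numeric cells, or missing label columns; raises it on
    an empty clips directory as well.
    """
    path = os.fspath(path)
    clip_dir = os.path.join(path, "clips")
    if not os.path.isdir(clip_dir):
        raise DatasetFormatError(f"no clips/ directory under {path}")
    files = sorted(f for f in os.listdir(clip_dir) if f.endswith(".csv"))
    if not files:
        raise DatasetFormatError(f"dataset at {path} contains no clips")

    clips = []
    for fname in files:
        fpath = os.path.join(clip_dir, fname)
        try:
            frame = pd.read_csv(fpath, dtype=np.float64)
        except ValueError as exc:
            raise DatasetFormatError(f"non-numeric data in {fpath}: {exc}") from exc
        if frame.shape[1] != N_FEATURES:
            raise DatasetFormatError(
                f"{fpath}: expected {N_FEATURES} feature columns, found {frame.shape[1]}"
            )
        clips.append(FeatureSequence(fname[: -len(".csv")], frame.to_numpy()))

    labels: dict[str, EmotionLabel] = {}
    label_path = os.path.join(path, "labels.csv")
    if os.path.exists(label_path):
        table = pd.read_csv(label_path)
        required = ("clip_id",) + EMOTIONS
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise DatasetFormatError(f"{label_path}: missing columns {missing}")
        for _, row in table.iterrows():
            labels[str(row["clip_id"])] = EmotionLabel(
                np.array([row[e] for e in EMOTIONS])
            )
    return Dataset(clips=clips, labels=labels)


def write_dataset(ds: Dataset, path: str | os.PathLike) -> None:
    """Write the directory format read by :func:`load_dataset`."""
    path = os.fspath(path)
    clip_dir = os.path.join(path, "clips")
    os.makedirs(clip_dir, exist_ok=True)
    columns = [f"f{i:02d}" for i in range(N_FEATURES)]
    for clip in ds.clips:
        pd.DataFrame(clip.values, columns=columns).to_csv(
            os.path.join(clip_dir, f"{clip.clip_id}.csv"), index=False
        )
    if ds.labels:
        rows = [
            {"clip_id": cid, **dict(zip(EMOTIONS, lab.intensities))}
            for cid, lab in sorted(ds.labels.items())
        ]
        pd.DataFrame(rows).to_csv(os.path.join(path, "labels.csv"), index=False)


# ---------------------------------------------------------------------------
# transforms


def split(ds: Dataset, fraction: float = 0.8, seed: int = 0) -> Dataset:
    """Assign a reproducible random clip-level train/validation split.

    ``fraction`` is the training share (default 80/20).  Returns the same
    Dataset object with ``split`` tags filled in; every clip lands in exactly
    one split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must lie strictly between 0 and 1")
    if len(ds.clips) < 2:
        raise ValueError("need at least 2 clips to split")
    ids = sorted(c.clip_id for c in ds.clips)
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(ids)]))
    order = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    ds.split = {}
    for rank, idx in enumerate(order):
        ds.split[ids[idx]] = TRAIN if rank < n_train else VALIDATION
    return ds


def standardize(ds: Dataset) -> tuple[Dataset, StandardizationStats]:
    """Fit per-feature z-scoring on the training split, apply everywhere.

    Validation clips are transformed with the training statistics.  Features
    with zero variance on the training split are flagged and mapped to 0.
    Non-finite raw entries become 0 after the transform.
    """
    train_clips = ds.subset(TRAIN) if ds.split else ds.clips
    if not train_clips:
        raise ValueError("training split is empty; cannot fit standardization")
    stacked = np.concatenate([c.values for c in train_clips], axis=0)
    finite = np.isfinite(stacked)
    masked = np.where(finite, stacked, np.nan)
    mean = np.nanmean(masked, axis=0)
    sd = np.nanstd(masked, axis=0)
    mean[~np.isfinite(mean)] = 0.0
    # relative tolerance: a column whose spread is at floating-point noise
    # level counts as constant
    zero_var = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    sd = np.where(zero_var, 1.0, sd)
    stats = StandardizationStats(mean=mean, sd=sd, zero_variance=zero_var)
    out_clips = [
        FeatureSequence(c.clip_id, stats.transform(c.values)) for c in ds.clips
    ]
    out = Dataset(clips=out_clips, labels=dict(ds.labels), split=dict(ds.split))
    return out, stats
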