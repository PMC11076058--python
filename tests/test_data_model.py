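"""Dataset types, the on-disk format, standardization and splitting."""

import numpy as np
import pandas as pd
import pytest

from emossl.data_model import (
    Dataset,
    DatasetFormatError,
    EmotionLabel,
    FeatureSequence,
    EMOTIONS,
    load_dataset,
    split,
    standardize,
    write_dataset,
)


def _make_dataset(n=6, T=20, seed=0, labeled_every=1):
    rng = np.random.default_rng(seed)
    clips, labels = [], {}
    for i in range(n):
        cid = f"c{i:03d}"
        clips.append(FeatureSequence(cid, rng.standard_normal((T + i, 74))))
        if i % labeled_every == 0:
            labels[cid] = EmotionLabel(rng.uniform(0, 3, size=6))
    return Dataset(clips=clips, labels=labels)


# ---------------------------------------------------------------------------
# types


def test_label_bounds_enforced():
    with pytest.raises(ValueError):
        EmotionLabel(np.array([0, 0, 0, 0, 0, 3.5]))
    with pytest.raises(ValueError):
        EmotionLabel(np.array([-0.1, 0, 0, 0, 0, 0]))
    with pytest.raises(ValueError):
        EmotionLabel(np.zeros(5))


def test_dataset_rejects_labels_for_unknown_clips():
    clip = FeatureSequence("a", np.zeros((5, 74)))
    with pytest.raises(ValueError):
        Dataset(clips=[clip], labels={"b": EmotionLabel(np.zeros(6))})


# ---------------------------------------------------------------------------
# on-disk format


def test_round_trip_preserves_values_and_counts(tmp_path):
    ds = _make_dataset(n=5, labeled_every=2)
    write_dataset(ds, tmp_path)
    back = load_dataset(tmp_path)
    assert len(back) == 5
    assert set(back.labels) == set(ds.labels)
    for orig, re in zip(ds.clips, back.clips):
        assert orig.clip_id == re.clip_id
        np.testing.assert_allclose(orig.values, re.values, rtol=0, atol=1e-12)
    for cid in ds.labels:
        np.testing.assert_allclose(
            ds.labels[cid].intensities, back.labels[cid].intensities, atol=1e-12
        )


def test_partial_labels_allowed(tmp_path):
    ds = _make_dataset(n=3, labeled_every=2)  # 2 of 3 labeled
    write_dataset(ds, tmp_path)
    back = load_dataset(tmp_path)
    assert len(back) == 3
    assert len(back.labels) == 2


def test_wrong_feature_count_names_file(tmp_path):
    (tmp_path / "clips").mkdir()
    pd.DataFrame(np.zeros((4, 73))).to_csv(tmp_path / "clips" / "bad.csv", index=False)
    with pytest.raises(DatasetFormatError, match="bad.csv"):
        load_dataset(tmp_path)


def test_non_numeric_cells_rejected(tmp_path):
    (tmp_path / "clips").mkdir()
    frame = pd.DataFrame(np.zeros((3, 74))).astype(object)
    frame.iloc[1, 5] = "oops"
    frame.to_csv(tmp_path / "clips" / "weird.csv", index=False)
    with pytest.raises(DatasetFormatError, match="weird.csv"):
        load_dataset(tmp_path)


def test_missing_label_columns_rejected(tmp_path):
    ds = _make_dataset(n=2)
    write_dataset(ds, tmp_path)
    pd.DataFrame({"clip_id": ["c000"], "happiness": [1.0]}).to_csv(
        tmp_path / "labels.csv", index=False
    )
    with pytest.raises(DatasetFormatError, match="labels.csv"):
        load_dataset(tmp_path)


def test_empty_directory_rejected(tmp_path):
    (tmp_path / "clips").mkdir()
    with pytest.raises(DatasetFormatError, match="no clips"):
        load_dataset(tmp_path)


def test_clip_ordering_lexicographic(tmp_path):
    ds = Dataset(
        clips=[
            FeatureSequence("zz", np.zeros((3, 74))),
            FeatureSequence("aa", np.zeros((3, 74))),
        ]
    )
    write_dataset(ds, tmp_path)
    back = load_dataset(tmp_path)
    assert [c.clip_id for c in back.clips] == ["aa", "zz"]


# ---------------------------------------------------------------------------
# split


def test_split_80_20_partition():
    ds = _make_dataset(n=100, T=4)
    split(ds, 0.8, seed=3)
    tags = list(ds.split.values())
    assert tags.count("train") == 80
    assert tags.count("validation") == 20
    assert set(ds.split) == {c.clip_id for c in ds.clips}


def test_split_deterministic_per_seed():
    a = _make_dataset(n=30)
    b = _make_dataset(n=30)
    split(a, 0.8, seed=9)
    split(b, 0.8, seed=9)
    assert a.split == b.split
    c = _make_dataset(n=30)
    split(c, 0.8, seed=10)
    assert a.split != c.split


def test_split_preconditions():
    ds = _make_dataset(n=10)
    with pytest.raises(ValueError):
        split(ds, 1.0, seed=0)
    with pytest.raises(ValueError):
        split(ds, 0.0, seed=0)
    single = Dataset(clips=[FeatureSequence("a", np.zeros((3, 74)))])
    with pytest.raises(ValueError):
        split(single, 0.8, seed=0)


# ---------------------------------------------------------------------------
# standardization


def test_standardize_zero_mean_unit_sd():
    ds = _make_dataset(n=20, T=30, seed=4)
    split(ds, 0.8, seed=0)
    out, stats = standardize(ds)
    stacked = np.concatenate([c.values for c in out.subset("train")], axis=0)
    np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(stacked.std(axis=0), 1.0, atol=1e-9)


def test_standardize_hand_z_score():
    rng = np.random.default_rng(0)
    values = rng.normal(10.0, 2.0, size=(100000, 74))
    values[0, 0] = 14.0
    ds = Dataset(clips=[FeatureSequence("a", values)])
    out, stats = standardize(ds)
    # value 14 in a column of mean ~10, sd ~2 standardizes to ~2
    expected = (14.0 - stats.mean[0]) / stats.sd[0]
    assert out.clips[0].values[0, 0] == pytest.approx(expected)
    assert expected == pytest.approx(2.0, abs=0.05)


def test_constant_feature_flagged_and_zeroed():
    rng = np.random.default_rng(1)
    values = rng.standard_normal((50, 74))
    values[:, 7] = 3.14
    ds = Dataset(clips=[FeatureSequence("a", values)])
    out, stats = standardize(ds)
    assert stats.zero_variance[7]
    assert stats.sd[7] == 1.0
    assert np.all(out.clips[0].values[:, 7] == 0.0)


def test_standardize_idempotent_up_to_tolerance():
    ds = _make_dataset(n=10, T=200, seed=5)
    once, _ = standardize(ds)
    twice, stats = standardize(once)
    np.testing.assert_allclose(stats.mean, 0.0, atol=1e-9)
    np.testing.assert_allclose(stats.sd, 1.0, atol=1e-9)
    for a, b in zip(once.clips, twice.clips):
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)


def test_non_finite_entries_map_to_zero():
    rng = np.random.default_rng(2)
    values = rng.standard_normal((40, 74))
    values[3, 10] = np.nan
    values[5, 11] = np.inf
    ds = Dataset(clips=[FeatureSequence("a", values)])
    out, _ = standardize(ds)
    assert out.clips[0].values[3, 10] == 0.0
    assert out.clips[0].values[5, 11] == 0.0
    assert np.all(np.isfinite(out.clips[0].values))


def test_standardization_invertible(tiny_dataset):
    ds, stats = tiny_dataset
    raw = stats.inverse_transform(ds.clips[0].values)
    again = stats.transform(raw)
    np.testing.assert_allclose(again, ds.clips[0].values, atol=1e-9)


def test_validation_uses_training_stats():
    ds = _make_dataset(n=20, T=30, seed=6)
    split(ds, 0.8, seed=0)
    out, stats = standardize(ds)
    val = ds.subset("validation")[0]
    out_val = out.clip(val.clip_id)
    np.testing.assert_allclose(out_val.values, stats.transform(val.values), atol=1e-12)
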