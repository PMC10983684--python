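"""Augmentation operators (against independent oracles), manifest
splitting/expansion, and the published dataset accounting."""

import numpy as np
import pandas as pd
import pytest

from noseleaf.augmentation import (TABLE1_ADDED, AugmentConfig,
                                   augment_training_set, dataset_statistics,
                                   gaussian_blur, gaussian_noise, gridmask,
                                   red_channel_rotate, resize_normalize,
                                   row_blackout)
from noseleaf.manifest import DatasetManifest, split_dataset
from noseleaf.synthetic import make_worked_example_tables

TABLE1 = make_worked_example_tables()["table1"]


@pytest.fixture
def white():
    return np.full((224, 224, 3), 255, np.uint8)


# --- gridmask ----------------------------------------------------------------

def test_gridmask_keep_one_is_identity(white):
    out = gridmask(white, keep_ratio=0.999, unit_range=(8, 16), seed=0)
    np.testing.assert_array_equal(out, white)


def test_gridmask_deterministic_and_masked_fraction(white):
    a = gridmask(white, 0.6, (96, 224), seed=42)
    b = gridmask(white, 0.6, (96, 224), seed=42)
    np.testing.assert_array_equal(a, b)
    # Monte-Carlo pixel-counting oracle: masked fraction -> 1 - keep^2
    fracs = [(gridmask(white, 0.6, (96, 224), seed=s) == 0).mean()
             for s in range(300)]
    assert abs(np.mean(fracs) - (1 - 0.6 ** 2)) < 0.05


def test_gridmask_unit_larger_than_image_raises():
    img = np.zeros((32, 32, 3), np.uint8)
    with pytest.raises(ValueError, match="larger than image"):
        gridmask(img, 0.6, (64, 128), seed=0)


# --- row blackout ------------------------------------------------------------

def test_row_blackout_every_fourth_row():
    img = np.full((8, 8, 3), 255, np.uint8)
    out = row_blackout(img, 4)
    black_rows = np.where((out == 0).all(axis=(1, 2)))[0]
    np.testing.assert_array_equal(black_rows, [3, 7])
    assert (out == 0).sum() == 2 * 8 * 3        # 16 black pixels per channel
    untouched = np.delete(np.arange(8), [3, 7])
    assert (out[untouched] == 255).all()


def test_row_blackout_period_edge_cases():
    img = np.full((5, 4, 3), 7, np.uint8)
    assert (row_blackout(img, 1) == 0).all()
    np.testing.assert_array_equal(row_blackout(img, 9), img)


# --- gaussian noise ----------------------------------------------------------

def test_gaussian_noise_identity_determinism_and_std(rng):
    img = np.full((183, 183, 3), 128, np.uint8)   # ~1e5 pixels
    np.testing.assert_array_equal(gaussian_noise(img, 0.0, seed=1), img)
    a = gaussian_noise(img, 0.05, seed=5)
    np.testing.assert_array_equal(a, gaussian_noise(img, 0.05, seed=5))
    resid = a.astype(float) - 128
    assert abs(resid.std() - 12.75) / 12.75 < 0.05


# --- red channel rotation ----------------------------------------------------

def test_red_rotate_zero_identity_and_other_channels_fixed(rng):
    img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    np.testing.assert_array_equal(red_channel_rotate(img, 0.0), img)
    out = red_channel_rotate(img, 33.0)
    np.testing.assert_array_equal(out[:, :, 1:], img[:, :, 1:])


def test_red_rotate_right_angle_matches_index_permutation(rng):
    img = rng.integers(0, 256, (9, 9, 3), dtype=np.uint8)
    out = red_channel_rotate(img, 90.0)
    # 90° counterclockwise about the center == exact index permutation
    np.testing.assert_array_equal(out[:, :, 0], np.rot90(img[:, :, 0], 1))


# --- gaussian blur -----------------------------------------------------------

def test_gaussian_blur_identities():
    img = np.full((12, 12, 3), 77, np.uint8)
    np.testing.assert_array_equal(gaussian_blur(img, 0.0), img)
    np.testing.assert_array_equal(gaussian_blur(img, 2.5), img)  # constant


def test_gaussian_blur_impulse_matches_dense_convolution():
    img = np.zeros((21, 21, 3), np.uint8)
    img[10, 10] = 255
    out = gaussian_blur(img, 1.0)
    # dense-kernel oracle (radius 4 sigma truncation, matching the default)
    r = 4
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-ax ** 2 / 2.0)
    k1 /= k1.sum()
    expected = 255.0 * np.outer(k1, k1)
    got = out[10 - r:10 + r + 1, 10 - r:10 + r + 1, 0].astype(float)
    assert np.abs(got - expected).max() <= 1.0


# --- resize / normalize ------------------------------------------------------

def test_resize_normalize_shapes_and_constant_zeroing():
    img = np.full((224, 224, 3), 100, np.uint8)
    out = resize_normalize(img, (224, 224), mean=(100 / 255,) * 3, std=(1, 1, 1))
    assert out.shape == (3, 224, 224)
    np.testing.assert_allclose(out, 0.0, atol=1e-6)


def test_resize_downscale_matches_area_oracle_probes():
    cb = (np.indices((448, 448)).sum(0) % 2) * 255
    img = np.stack([cb] * 3, axis=-1).astype(np.uint8)
    out = resize_normalize(img, (224, 224), mean=(0, 0, 0), std=(1, 1, 1))
    # 2x downscale of a 1-px checkerboard: every probe is the area-weighted
    # average of equal black/white mass, 127.5/255
    for y, x in [(50, 50), (100, 173), (5, 210), (120, 7)]:
        assert abs(out[0, y, x] - 0.5) < 0.02


def test_dataset_statistics_round_trip(rng):
    imgs = rng.integers(0, 256, (10, 8, 8, 3), dtype=np.uint8)
    mean, std = dataset_statistics(imgs)
    x = np.stack([resize_normalize(im, (8, 8), mean=mean, std=std)
                  for im in imgs])
    assert abs(x.mean()) < 1e-3
    assert abs(x.std() - 1) < 1e-3


# --- splitting and the published accounting ----------------------------------

def _table1_manifest():
    return DatasetManifest.from_counts(TABLE1["originals"].to_dict())


def test_split_with_published_test_counts_reproduces_totals():
    split = split_dataset(_table1_manifest(),
                          test_counts=TABLE1["test"].to_dict(), seed=0)
    table = split.accounting_table()
    assert table.loc["Total", "originals"] == 879
    assert table.loc["Total", "train_originals"] == 586
    assert table.loc["Total", "test"] == 293
    pd.testing.assert_series_equal(
        table.drop("Total")["test"], TABLE1["test"],
        check_names=False, check_dtype=False)


def test_split_fraction_rounding_and_degenerate():
    m = DatasetManifest.from_counts({"a": 90, "b": 10})
    split = split_dataset(m, test_fraction=1 / 3, seed=1)
    assert split.per_class_counts("test")["a"] == 30
    all_train = split_dataset(m, test_fraction=0.0, seed=1)
    assert (all_train.records["split"] == "train").all()


def test_split_is_seeded_and_partitions():
    m = _table1_manifest()
    s1 = split_dataset(m, test_fraction=1 / 3, seed=9)
    s2 = split_dataset(m, test_fraction=1 / 3, seed=9)
    pd.testing.assert_frame_equal(s1.records, s2.records)
    assert set(s1.records["path"]) == set(m.records["path"])
    tr = set(s1.records.loc[s1.records["split"] == "train", "path"])
    te = set(s1.records.loc[s1.records["split"] == "test", "path"])
    assert tr.isdisjoint(te) and len(tr) + len(te) == len(m)


def test_augment_reproduces_published_final_training_set():
    split = split_dataset(_table1_manifest(),
                          test_counts=TABLE1["test"].to_dict(), seed=0)
    out = augment_training_set(split, AugmentConfig(), seed=0)
    table = out.accounting_table()
    pd.testing.assert_series_equal(
        table.drop("Total")["train_final"], TABLE1["train_final"],
        check_names=False, check_dtype=False)
    assert table.loc["Total", "train_final"] == 1280
    assert table.loc["Total", "test"] == 293


def test_augment_zero_multiplicity_is_identity_and_no_leakage():
    split = split_dataset(_table1_manifest(),
                          test_counts=TABLE1["test"].to_dict(), seed=0)
    same = augment_training_set(
        split, AugmentConfig(per_class_multiplicity={}), seed=0)
    pd.testing.assert_frame_equal(same.records, split.records)
    out = augment_training_set(split, AugmentConfig(), seed=3)
    aug = out.records[out.records["provenance"] == "augmented"]
    assert (aug["split"] == "train").all()
    test_paths = set(out.records.loc[out.records["split"] == "test", "path"])
    assert set(aug["source_path"]).isdisjoint(test_paths)


def test_augment_unknown_class_raises():
    split = split_dataset(_table1_manifest(), test_fraction=0.0, seed=0)
    cfg = AugmentConfig(per_class_multiplicity={"R_martian": 3})
    with pytest.raises(ValueError, match="unknown classes"):
        augment_training_set(split, cfg, seed=0)


def test_manifest_csv_round_trip_is_bit_identical(tmp_path):
    split = split_dataset(_table1_manifest(),
                          test_counts=TABLE1["test"].to_dict(), seed=4)
    out = augment_training_set(split, AugmentConfig(), seed=4)
    p1 = tmp_path / "m1.csv"
    p2 = tmp_path / "m2.csv"
    out.to_csv(p1)
    DatasetManifest.from_csv(p1).to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_augment_renders_pixels_when_roots_given(tmp_path, rng):
    from PIL import Image
    root = tmp_path / "in"
    for cls in ("a", "b"):
        (root / cls).mkdir(parents=True)
        for i in range(3):
            arr = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
            Image.fromarray(arr).save(root / cls / f"img{i}.png")
    m = DatasetManifest.from_directory(root)
    split = split_dataset(m, test_fraction=1 / 3, seed=0)
    cfg = AugmentConfig(per_class_multiplicity={"a": 2, "b": 2},
                        gridmask_unit_range=(8, 24))
    out_root = tmp_path / "out"
    aug = augment_training_set(split, cfg, seed=5, images_root=root,
                               out_root=out_root)
    rendered = list(out_root.rglob("*.png"))
    assert len(rendered) == 4
    for rec in aug.records[aug.records["provenance"] == "augmented"].itertuples():
        img = np.asarray(Image.open(out_root / rec.path))
        assert img.shape == (40, 40, 3)
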