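"""Tiling, coverage filtering, splitting and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agrinet.dataset_builder import (AugmentOps, TilePair, augment,
                                     crop_fraction, filter_coverage, split,
                                     tile_scene)


def make_pair(mask, n_channels=10, seed=0):
    rng = np.random.default_rng(seed)
    image = rng.uniform(0, 100, (n_channels,) + mask.shape).astype(np.float32)
    return TilePair(image=image, mask=mask, tile_id="t",
                    crop_fraction=crop_fraction(mask))


# -- tiling ----------------------------------------------------------------

def test_tile_counts_and_partial_strip_drop():
    mask = np.zeros((64, 64), dtype=np.uint8)
    scene = np.zeros((10, 64, 64), dtype=np.float32)
    assert len(tile_scene(scene, mask, 32)) == 4
    # trailing strip narrower than the tile is dropped
    mask2 = np.zeros((65, 64), dtype=np.uint8)
    scene2 = np.zeros((10, 65, 64), dtype=np.float32)
    assert len(tile_scene(scene2, mask2, 32)) == 4


def test_tile_area_conservation():
    h, w, ts = 150, 100, 32
    tiles = tile_scene(np.zeros((3, h, w)), np.zeros((h, w), np.uint8), ts)
    assert sum(t.mask.size for t in tiles) == (h // ts) * (w // ts) * ts * ts


def test_tile_crop_fraction_counts_both_crop_classes():
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[:8] = 1            # 25 % canola
    mask[8:13] = 2          # ~15.6 % wheat
    (tile,) = tile_scene(np.zeros((10, 32, 32)), mask, 32)
    assert tile.crop_fraction == pytest.approx(np.isin(mask, (1, 2)).mean())


def test_tile_scene_shape_mismatch_errors():
    with pytest.raises(ValueError, match="differ"):
        tile_scene(np.zeros((10, 64, 64)), np.zeros((32, 64), np.uint8), 32)


# -- coverage filter -------------------------------------------------------

def fraction_tiles():
    tiles = []
    for i, frac in enumerate(np.arange(0, 1.0, 0.1)):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[:int(round(frac * 32))] = 1
        tiles.append(TilePair(image=np.zeros((10, 32, 32)), mask=mask,
                              tile_id=f"t{i}", crop_fraction=crop_fraction(mask)))
    return tiles


def test_filter_retains_fractions_at_or_above_threshold():
    kept = filter_coverage(fraction_tiles(), 0.30)
    assert len(kept) == 7                       # 0.3 .. 0.9
    assert all(t.crop_fraction >= 0.30 for t in kept)
    assert [t.tile_id for t in kept] == sorted([t.tile_id for t in kept])


def test_filter_boundary_inclusive_and_background_removed():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[:3] = 2                                # exactly 0.30
    boundary = TilePair(image=np.zeros((10, 10, 10)), mask=mask,
                        tile_id="b", crop_fraction=crop_fraction(mask))
    empty = TilePair(image=np.zeros((10, 10, 10)),
                     mask=np.zeros((10, 10), np.uint8), tile_id="e",
                     crop_fraction=0.0)
    assert filter_coverage([boundary, empty], 0.30) == [boundary]


def test_filter_is_idempotent():
    kept = filter_coverage(fraction_tiles(), 0.30)
    assert filter_coverage(kept, 0.30) == kept


# -- splitting -------------------------------------------------------------

def n_tiles(n):
    return [TilePair(image=np.zeros((10, 8, 8)),
                     mask=np.zeros((8, 8), np.uint8), tile_id=f"t{i}",
                     crop_fraction=0.0) for i in range(n)]


@pytest.mark.parametrize("n,expected_train", [(100, 70), (10, 7)])
def test_split_ratio(n, expected_train):
    manifest = split(n_tiles(n), 0.7, seed=5)
    assert len(manifest.train_ids) == expected_train
    assert len(manifest.val_ids) == n - expected_train
    assert not set(manifest.train_ids) & set(manifest.val_ids)


def test_split_deterministic_under_seed():
    tiles = n_tiles(20)
    a, b = split(tiles, 0.7, seed=9), split(tiles, 0.7, seed=9)
    assert a.train_ids == b.train_ids and a.val_ids == b.val_ids
    c = split(tiles, 0.7, seed=10)
    assert c.train_ids != a.train_ids  # different seed permutes differently


def test_split_requires_two_tiles():
    with pytest.raises(ValueError):
        split(n_tiles(1), 0.7, seed=0)


# -- augmentation ----------------------------------------------------------

def test_full_rotation_and_double_mirror_are_identity():
    mask = np.random.default_rng(1).integers(0, 3, (16, 16)).astype(np.uint8)
    pair = make_pair(mask)
    rot4 = augment(pair, AugmentOps(rotate90_k=4))
    assert np.array_equal(rot4.image, pair.image)
    assert np.array_equal(rot4.mask, pair.mask)
    once = augment(pair, AugmentOps(horizontal_mirror=True))
    twice = augment(once, AugmentOps(horizontal_mirror=True))
    assert np.array_equal(twice.image, pair.image)
    assert np.array_equal(twice.mask, pair.mask)


def test_zero_sigma_noise_is_identity():
    pair = make_pair(np.zeros((8, 8), dtype=np.uint8))
    out = augment(pair, AugmentOps(noise_sigma=0.0), seed=3)
    assert np.array_equal(out.image, pair.image)


def test_noise_touches_image_only():
    mask = np.random.default_rng(2).integers(0, 3, (16, 16)).astype(np.uint8)
    pair = make_pair(mask)
    out = augment(pair, AugmentOps(noise_sigma=0.05), seed=3)
    assert not np.array_equal(out.image, pair.image)
    assert np.array_equal(out.mask, pair.mask)


@settings(deadline=None, max_examples=25)
@given(k=st.integers(0, 3), hm=st.booleans(), vm=st.booleans(),
       seed=st.integers(0, 10))
def test_geometric_augmentation_conserves_class_pixel_counts(k, hm, vm, seed):
    mask = np.random.default_rng(seed).integers(0, 3, (24, 24)).astype(np.uint8)
    pair = make_pair(mask, seed=seed)
    out = augment(pair, AugmentOps(rotate90_k=k, horizontal_mirror=hm,
                                   vertical_mirror=vm))
    assert np.array_equal(np.bincount(out.mask.ravel(), minlength=3),
                          np.bincount(mask.ravel(), minlength=3))
    assert set(np.unique(out.mask)) <= {0, 1, 2}
    assert out.crop_fraction == pair.crop_fraction
    # image moved with the mask: per-band sums conserved
    assert np.allclose(out.image.sum(axis=(1, 2)), pair.image.sum(axis=(1, 2)),
                       rtol=1e-5)
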