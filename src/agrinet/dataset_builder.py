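"""Tiling, coverage filtering, train/validation splitting and augmentation.

Preprocessed scenes are cut into non-overlapping ``tile_size`` squares in
row-major order (trailing partial tiles dropped), paired with their label
masks (0 background, 1 winter canola, 2 winter wheat), filtered by crop
coverage, and split uniformly at random into train/validation sets.
Geometric augmentations (right-angle rotations, mirrors) act identically on
image and mask; additive Gaussian noise acts on the image only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geotiff import read_geotiff, write_geotiff
from .sentinel_io import BandStack

DEFAULT_TILE_SIZE = 512
DEFAULT_COVERAGE_THRESHOLD = 0.30
DEFAULT_SPLIT_RATIO = 0.7
CROP_CLASSES = (1, 2)


@dataclass
class TilePair:
    """One image tile plus its label mask."""

    image: np.ndarray        # (10, T, T) stretched DN, float32
    mask: np.ndarray         # (T, T) labels in {0, 1, 2}, uint8
    tile_id: str
    crop_fraction: float
    geotransform: tuple | None = None
    crs: str | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.ndim != 3:
            raise ValueError("tile image must be (C, H, W)")
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError("image and mask sizes differ")
        if not set(np.unique(self.mask)) <= {0, 1, 2}:
            raise ValueError("mask values must lie in {0, 1, 2}")


@dataclass
class DatasetManifest:
    train_ids: list
    val_ids: list
    split_ratio: float
    seed: int
    coverage_threshold: float
    tile_size: int = DEFAULT_TILE_SIZE
    crop_fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation tiles overlap")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        return cls(**json.loads(Path(path).read_text()))


def crop_fraction(mask: np.ndarray) -> float:
    mask = np.asarray(mask)
    return float(np.isin(mask, CROP_CLASSES).mean())


def tile_scene(scene, mask_raster, tile_size: int = DEFAULT_TILE_SIZE,
               scene_id: str = "scene") -> list:
    """Cut a scene/mask pair into non-overlapping tiles, row-major order;
    trailing strips narrower than ``tile_size`` are dropped."""
    image = scene.as_array() if isinstance(scene, BandStack) else np.asarray(scene)
    mask = np.asarray(mask_raster)
    if image.shape[1:] != mask.shape:
        raise ValueError(
            f"scene {image.shape[1:]} and mask {mask.shape} sizes differ")
    geo = scene.geotransform if isinstance(scene, BandStack) else None
    crs = scene.crs if isinstance(scene, BandStack) else None
    h, w = mask.shape
    tiles = []
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            rs, cs = r * tile_size, c * tile_size
            sub_mask = mask[rs:rs + tile_size, cs:cs + tile_size]
            tile_geo = None
            if geo is not None:
                x0, dx, rx, y0, ry, dy = geo
                tile_geo = (x0 + cs * dx, dx, rx, y0 + rs * dy, ry, dy)
            tiles.append(TilePair(
                image=image[:, rs:rs + tile_size, cs:cs + tile_size],
                mask=sub_mask,
                tile_id=f"{scene_id}_r{r:03d}_c{c:03d}",
                crop_fraction=crop_fraction(sub_mask),
                geotransform=tile_geo, crs=crs))
    return tiles


def filter_coverage(tiles, threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> list:
    """Retain tiles whose crop coverage is at least ``threshold``
    (strict-less-than-threshold tiles are removed)."""
    return [t for t in tiles if t.crop_fraction >= threshold]


def split(tiles, ratio: float = DEFAULT_SPLIT_RATIO, seed: int = 0,
          coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> DatasetManifest:
    """Uniformly random train/validation split: first floor(ratio*n) of a
    seeded permutation train, the rest validation."""
    tiles = list(tiles)
    if len(tiles) < 2:
        raise ValueError("need at least 2 tiles to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    n_train = int(np.floor(ratio * len(tiles)))
    ids = [tiles[i].tile_id for i in order]
    tile_size = tiles[0].mask.shape[0]
    return DatasetManifest(
        train_ids=ids[:n_train], val_ids=ids[n_train:], split_ratio=ratio,
        seed=seed, coverage_threshold=coverage_threshold, tile_size=tile_size,
        crop_fractions={t.tile_id: t.crop_fraction for t in tiles})


# -- augmentation ----------------------------------------------------------

@dataclass(frozen=True)
class AugmentOps:
    """Deterministic augmentation recipe.

    ``noise_sigma`` is additive zero-mean Gaussian noise expressed as a
    fraction of each band's DN range within the tile; geometric operations
    are applied identically to image and mask, noise to the image only.
    """

    rotate90_k: int = 0
    horizontal_mirror: bool = False
    vertical_mirror: bool = False
    noise_sigma: float = 0.0


def augment(pair: TilePair, ops: AugmentOps, seed: int = 0) -> TilePair:
    image, mask = pair.image, pair.mask
    k = ops.rotate90_k % 4
    if k:
        image = np.rot90(image, k, axes=(1, 2))
        mask = np.rot90(mask, k)
    if ops.horizontal_mirror:
        image = image[:, :, ::-1]
        mask = mask[:, ::-1]
    if ops.vertical_mirror:
        image = image[:, ::-1, :]
        mask = mask[::-1, :]
    image = np.ascontiguousarray(image)
    if ops.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        span = image.max(axis=(1, 2)) - image.min(axis=(1, 2))
        sigma = (ops.noise_sigma * span)[:, None, None]
        image = image + rng.normal(0.0, 1.0, image.shape).astype(np.float32) * sigma
    return TilePair(image=image, mask=np.ascontiguousarray(mask),
                    tile_id=pair.tile_id, crop_fraction=pair.crop_fraction,
                    geotransform=pair.geotransform, crs=pair.crs)


def random_augment(pair: TilePair, rng: np.random.Generator,
                   noise_sigma: float = 0.01) -> TilePair:
    """Sample a random recipe (any rotation x mirrors + noise) and apply it."""
    ops = AugmentOps(rotate90_k=int(rng.integers(4)),
                     horizontal_mirror=bool(rng.integers(2)),
                     vertical_mirror=bool(rng.integers(2)),
                     noise_sigma=noise_sigma)
    return augment(pair, ops, seed=int(rng.integers(2 ** 31)))


# -- persistence -----------------------------------------------------------

def save_tiles(out_dir, tiles, manifest: DatasetManifest) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for t in tiles:
        geo = t.geotransform or (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
        write_geotiff(out / "images" / f"{t.tile_id}.tif", t.image, geo, t.crs,
                      metadata={"tile_id": t.tile_id,
                                "crop_fraction": t.crop_fraction})
        write_geotiff(out / "masks" / f"{t.tile_id}.tif", t.mask, geo, t.crs,
                      dtype=np.uint8)
    manifest.to_json(out / "manifest.json")


def load_tiles(data_dir, tile_ids=None):
    data = Path(data_dir)
    manifest = DatasetManifest.from_json(data / "manifest.json")
    if tile_ids is None:
        tile_ids = manifest.train_ids + manifest.val_ids
    tiles = []
    for tid in tile_ids:
        img = read_geotiff(data / "images" / f"{tid}.tif")
        msk = read_geotiff(data / "masks" / f"{tid}.tif")
        tiles.append(TilePair(image=img.data, mask=msk.data, tile_id=tid,
                              crop_fraction=crop_fraction(msk.data),
                              geotransform=img.geotransform, crs=img.crs))
    return tiles, manifest
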