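"""Synthetic 10-band scenes with field/road structure for testing.

The generator emulates the geometry and spectral contrast of winter-crop
scenes: contiguous polygonal fields of two crop classes (winter canola,
winter wheat) separated by thin background roads, with class-specific
10-band mean digital-number signatures plus additive Gaussian noise.  The
default signatures place the canola/wheat contrast in the red-edge and NIR
bands, as for real vegetation, but are fixed constants — no radiometric
realism is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import dataset_builder as db
from .sentinel_io import CANONICAL_BANDS, NATIVE_RESOLUTION, BandStack, fuse

#: per-class mean DN per fused band (B2..B12); rows: background, canola, wheat
DEFAULT_SIGNATURES = np.array([
    [1100, 1300, 1600, 1900, 2200, 2400, 2500, 2600, 3000, 2600],  # 0 bg
    [600, 900, 700, 1500, 3200, 3800, 4000, 4100, 2400, 1500],     # 1 canola
    [400, 700, 500, 1100, 2400, 3200, 3500, 3600, 1900, 1000],     # 2 wheat
], dtype=np.float64)


@dataclass
class FixtureSpec:
    scene_hw: tuple = (1536, 1536)
    n_fields: int = 64
    geometry: str = "grid"            # "grid" or "voronoi"
    field_size_px: tuple = (96, 256)  # grid geometry: cell side range
    road_width_px: int = 3
    class_priors: tuple = (0.5, 0.5)  # P(canola), P(wheat) per field
    signatures: np.ndarray = field(default_factory=lambda: DEFAULT_SIGNATURES.copy())
    noise_sigma: float = 60.0         # DN units, i.i.d. per pixel/band
    seed: int = 0

    def __post_init__(self):
        self.signatures = np.asarray(self.signatures, dtype=np.float64)
        if self.signatures.shape != (3, 10):
            raise ValueError("signatures must be (3 classes, 10 bands)")
        if not np.any(self.signatures[1] != self.signatures[2]):
            raise ValueError("class signatures must differ in at least one band")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.road_width_px < 1:
            raise ValueError("road width must be at least 1 pixel")
        if abs(sum(self.class_priors) - 1.0) > 1e-9 or min(self.class_priors) < 0:
            raise ValueError("class priors must be a distribution over 2 classes")
        if self.geometry not in ("grid", "voronoi"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _grid_cuts(extent: int, lo: int, hi: int, rng) -> list:
    cuts, pos = [0], 0
    while pos < extent:
        pos += int(rng.integers(lo, hi + 1))
        cuts.append(min(pos, extent))
    return cuts


def _label_grid(spec: FixtureSpec, rng) -> np.ndarray:
    h, w = spec.scene_hw
    lo, hi = spec.field_size_px
    mask = np.zeros((h, w), dtype=np.uint8)
    rw = spec.road_width_px
    ys = _grid_cuts(h, lo, hi, rng)
    xs = _grid_cuts(w, lo, hi, rng)
    for y0, y1 in zip(ys[:-1], ys[1:]):
        for x0, x1 in zip(xs[:-1], xs[1:]):
            if y1 - rw <= y0 or x1 - rw <= x0:
                continue
            cls = 1 if rng.random() < spec.class_priors[0] else 2
            mask[y0:y1 - rw, x0:x1 - rw] = cls
    return mask


def _label_voronoi(spec: FixtureSpec, rng) -> np.ndarray:
    h, w = spec.scene_hw
    seeds = np.column_stack([rng.uniform(0, h, spec.n_fields),
                             rng.uniform(0, w, spec.n_fields)])
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
    cell = d2.argmin(axis=-1)
    classes = np.where(rng.random(spec.n_fields) < spec.class_priors[0], 1, 2)
    mask = classes[cell].astype(np.uint8)
    # roads: pixels near a boundary between different cells
    edge = (ndimage.maximum_filter(cell, size=2) !=
            ndimage.minimum_filter(cell, size=2))
    road = ndimage.binary_dilation(edge, iterations=max(spec.road_width_px - 1, 1))
    mask[road] = 0
    return mask


def generate_labels(spec: FixtureSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "grid":
        return _label_grid(spec, rng)
    return _label_voronoi(spec, rng)


def render_image(labels: np.ndarray, spec: FixtureSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """(10, H, W) DN image: class mean signature + Gaussian noise, >= 0."""
    image = spec.signatures[labels].transpose(2, 0, 1).astype(np.float32)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma,
                                   image.shape).astype(np.float32)
    return np.clip(image, 0.0, None)


def generate_scene(spec: FixtureSpec):
    """Deterministic (BandStack, label raster) under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels = _label_grid(spec, rng) if spec.geometry == "grid" \
        else _label_voronoi(spec, rng)
    image = render_image(labels, spec, rng)
    stack = fuse(list(image), geotransform=(600000.0, 10.0, 0.0, 3500000.0, 0.0, -10.0),
                 crs="EPSG:32649", metadata={"synthetic": True, "seed": spec.seed})
    return stack, labels


def _block_mean(band: np.ndarray, f: int) -> np.ndarray:
    h, w = band.shape
    return band[:h - h % f, :w - w % f].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def generate_raw_scene(spec: FixtureSpec):
    """13-band stack at native 10/20/60 m resolutions (block means of the
    10 m rendering), for exercising the full preprocessing chain."""
    stack, labels = generate_scene(spec)
    fused = dict(zip(stack.band_ids, stack.bands))
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 60)))
    bands, ids, res = [], [], []
    order = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B9",
             "B10", "B11", "B12")
    for bid in order:
        r = NATIVE_RESOLUTION[bid]
        if bid in fused:
            b = fused[bid] if r == 10 else _block_mean(fused[bid], r // 10)
        else:  # 60 m atmospheric bands: uninformative noise
            h, w = spec.scene_hw
            b = rng.uniform(0, 500, (h // 6, w // 6))
        bands.append(b)
        ids.append(bid)
        res.append(r)
    return BandStack(bands=bands, band_ids=ids, resolution_m=res,
                     geotransform=stack.geotransform, crs=stack.crs,
                     metadata={"synthetic": True}), labels


def generate_ds_like(spec: FixtureSpec, n_tiles: int,
                     coverage_threshold: float = db.DEFAULT_COVERAGE_THRESHOLD,
                     tile_size: int = db.DEFAULT_TILE_SIZE,
                     split_ratio: float = db.DEFAULT_SPLIT_RATIO,
                     out_dir=None, max_scenes: int = 50):
    """Emit ``n_tiles`` tiles that already pass the coverage filter, plus a
    train/validation manifest; optionally persisted in the dataset layout."""
    if coverage_threshold >= 1.0:
        raise ValueError(
            "coverage threshold 1.0 is unsatisfiable: roads guarantee "
            "background pixels in every tile")
    tiles = []
    for i in range(max_scenes):
        sub = FixtureSpec(**{**spec.__dict__,
                             "signatures": spec.signatures.copy(),
                             "seed": spec.seed + i})
        stack, labels = generate_scene(sub)
        new = db.filter_coverage(
            db.tile_scene(stack, labels, tile_size, scene_id=f"syn{sub.seed:04d}"),
            coverage_threshold)
        tiles.extend(new)
        if len(tiles) >= n_tiles:
            break
    if len(tiles) < n_tiles:
        raise RuntimeError(
            f"only {len(tiles)} tiles passed the coverage filter after "
            f"{max_scenes} scenes; relax the threshold or enlarge the scenes")
    tiles = tiles[:n_tiles]
    manifest = db.split(tiles, split_ratio, seed=spec.seed,
                        coverage_threshold=coverage_threshold)
    if out_dir is not None:
        db.save_tiles(out_dir, tiles, manifest)
    return tiles, manifest


def classify_nearest_mean(image: np.ndarray,
                          signatures: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel nearest-signature classifier; with well-separated
    signatures and vanishing noise its accuracy approaches 1, which
    upper-bounds any sensible model on these fixtures."""
    sig = np.asarray(DEFAULT_SIGNATURES if signatures is None else signatures)
    img = np.asarray(image, dtype=np.float64)
    d2 = ((img[None] - sig[:, :, None, None]) ** 2).sum(axis=1)
    return d2.argmin(axis=0).astype(np.uint8)
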