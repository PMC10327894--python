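"""Sentinel-2 band screening, resampling, fusion and linear DN stretching.

The preprocessing chain drops the three 60 m atmospheric bands (B1, B9,
B10), resamples the 20 m bands to 10 m with bilinear interpolation, fuses
the ten surviving bands into a single 10-channel stack, and optionally
harmonizes the digital-number (DN) range of a stack against a reference
scene with a percentage linear stretch

    result = (DN - min_in) / (max_in - min_in) * (max_out - min_out) + min_out

where the input bounds come from the stretched image (optionally after
clipping a fraction of each histogram tail) and the output bounds from the
reference image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geotiff import IDENTITY_TRANSFORM, Raster, read_geotiff, write_geotiff
from .nn.functional import bilinear_matrix

#: canonical channel order of the fused 10-band product
CANONICAL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")
EXCLUDED_BANDS = ("B1", "B9", "B10")

#: native ground sampling distance (m) of each Sentinel-2 band
NATIVE_RESOLUTION = {
    "B1": 60, "B2": 10, "B3": 10, "B4": 10, "B5": 20, "B6": 20, "B7": 20,
    "B8": 10, "B8A": 20, "B9": 60, "B10": 60, "B11": 20, "B12": 20,
}


@dataclass
class BandStack:
    """Ordered multiband raster with per-band resolution metadata."""

    bands: list                       # list of 2-D DN arrays
    band_ids: tuple
    resolution_m: tuple
    geotransform: tuple = IDENTITY_TRANSFORM
    crs: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bands = [np.asarray(b) for b in self.bands]
        self.band_ids = tuple(self.band_ids)
        self.resolution_m = tuple(self.resolution_m)
        if len(self.bands) != len(self.band_ids) or \
                len(self.bands) != len(self.resolution_m):
            raise ValueError("bands, band_ids and resolution_m must align")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band(self, band_id: str) -> np.ndarray:
        return self.bands[self.band_ids.index(band_id)]

    def as_array(self) -> np.ndarray:
        """(C, H, W) array; requires all bands to share one shape."""
        shapes = {b.shape for b in self.bands}
        if len(shapes) > 1:
            raise ValueError(f"bands have mixed shapes {sorted(shapes)}")
        return np.stack(self.bands)


@dataclass(frozen=True)
class StretchParams:
    min_in: float
    max_in: float
    min_out: float
    max_out: float
    clip_percent: float = 0.0

    def __post_init__(self):
        if not self.max_in > self.min_in:
            raise ValueError("max_in must exceed min_in (degenerate band)")
        if not self.max_out > self.min_out:
            raise ValueError("max_out must exceed min_out")
        if not 0.0 <= self.clip_percent < 0.5:
            raise ValueError("clip_percent must lie in [0, 0.5)")


def select_bands(raw: BandStack) -> BandStack:
    """Drop B1/B9/B10 and order the survivors canonically."""
    missing = [b for b in CANONICAL_BANDS if b not in raw.band_ids]
    if missing:
        raise ValueError(f"required band {missing[0]} absent")
    idx = [raw.band_ids.index(b) for b in CANONICAL_BANDS]
    return BandStack(bands=[raw.bands[i] for i in idx],
                     band_ids=CANONICAL_BANDS,
                     resolution_m=tuple(raw.resolution_m[i] for i in idx),
                     geotransform=raw.geotransform, crs=raw.crs,
                     metadata=dict(raw.metadata))


def resample_to_10m(band: np.ndarray, src_res_m: float) -> np.ndarray:
    """Bilinear upsampling of a 20 m band to 10 m (half-pixel-center
    alignment); 10 m input is returned unchanged."""
    band = np.asarray(band)
    if band.size == 0:
        raise ValueError("empty band")
    if src_res_m == 10:
        return band
    if src_res_m != 20:
        raise ValueError(f"unsupported source resolution {src_res_m} m")
    h, w = band.shape
    rmat = bilinear_matrix(h, 2 * h).astype(np.float64)
    cmat = bilinear_matrix(w, 2 * w).astype(np.float64)
    return rmat @ band.astype(np.float64) @ cmat.T


def fuse(bands, band_ids=CANONICAL_BANDS, geotransform=IDENTITY_TRANSFORM,
         crs=None, metadata=None) -> BandStack:
    """Stack 10 co-registered 10 m bands into one canonical BandStack."""
    bands = [np.asarray(b) for b in bands]
    if len(bands) != 10:
        raise ValueError(f"expected 10 bands to fuse, got {len(bands)}")
    ref_shape = bands[0].shape
    bad = [bid for b, bid in zip(bands, band_ids) if b.shape != ref_shape]
    if bad:
        raise ValueError(f"shape mismatch for bands {bad}")
    return BandStack(bands=bands, band_ids=tuple(band_ids),
                     resolution_m=(10,) * 10, geotransform=geotransform,
                     crs=crs, metadata=metadata or {})


def preprocess_stack(raw: BandStack) -> BandStack:
    """select_bands -> resample_to_10m -> fuse, in one call."""
    sel = select_bands(raw)
    resampled = [resample_to_10m(b, r)
                 for b, r in zip(sel.bands, sel.resolution_m)]
    return fuse(resampled, geotransform=sel.geotransform, crs=sel.crs,
                metadata=dict(sel.metadata))


def compute_stretch_bounds(band: np.ndarray, clip_percent: float = 0.0):
    """Input DN bounds for a stretch, optionally clipping histogram tails."""
    band = np.asarray(band, dtype=np.float64)
    if clip_percent > 0:
        lo, hi = np.quantile(band, [clip_percent, 1.0 - clip_percent])
    else:
        lo, hi = float(band.min()), float(band.max())
    return float(lo), float(hi)


def linear_stretch(band: np.ndarray, p: StretchParams) -> np.ndarray:
    """Elementwise percentage linear stretch; out-of-range DN are clipped to
    the output bounds."""
    band = np.asarray(band, dtype=np.float64)
    scale = (p.max_out - p.min_out) / (p.max_in - p.min_in)
    out = (band - p.min_in) * scale + p.min_out
    return np.clip(out, p.min_out, p.max_out)


def harmonize(reference: BandStack, target: BandStack,
              clip_percent: float = 0.0) -> BandStack:
    """Stretch every target band so its DN range matches the corresponding
    reference band; the per-band StretchParams land in the output metadata."""
    if reference.band_ids != target.band_ids:
        raise ValueError(
            f"band mismatch: reference {reference.band_ids} vs "
            f"target {target.band_ids}")
    stretched, params = [], {}
    for bid in target.band_ids:
        ref_lo, ref_hi = compute_stretch_bounds(reference.band(bid))
        if ref_hi <= ref_lo:
            raise ValueError(f"reference band {bid} has a degenerate DN range")
        tgt_lo, tgt_hi = compute_stretch_bounds(target.band(bid), clip_percent)
        p = StretchParams(min_in=tgt_lo, max_in=tgt_hi, min_out=ref_lo,
                          max_out=ref_hi, clip_percent=clip_percent)
        stretched.append(linear_stretch(target.band(bid), p))
        params[bid] = [p.min_in, p.max_in, p.min_out, p.max_out, p.clip_percent]
    meta = dict(target.metadata)
    meta["stretch_params"] = params
    return BandStack(bands=stretched, band_ids=target.band_ids,
                     resolution_m=target.resolution_m,
                     geotransform=target.geotransform, crs=target.crs,
                     metadata=meta)


# -- GeoTIFF round-trip ----------------------------------------------------

def save_stack(path, stack: BandStack, dtype=None) -> None:
    """One TIFF page per band, so mixed-resolution (pre-fusion) stacks are
    representable; geotransform/CRS/metadata ride on the first page."""
    import json

    import tifffile

    from .geotiff import GEO_KEY_DIRECTORY, MODEL_PIXEL_SCALE, MODEL_TIEPOINT

    meta = dict(stack.metadata)
    meta["band_ids"] = list(stack.band_ids)
    meta["resolution_m"] = list(stack.resolution_m)
    desc = json.dumps({"geotransform": list(stack.geotransform),
                       "crs": stack.crs, "metadata": meta})
    x0, dx, rx, y0, ry, dy = stack.geotransform
    extratags = [(MODEL_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
                 (MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0))]
    if stack.crs and stack.crs.upper().startswith("EPSG:"):
        epsg = int(stack.crs.split(":")[1])
        keys = (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, epsg)
        extratags.append((GEO_KEY_DIRECTORY, "H", len(keys), keys))
    with tifffile.TiffWriter(path) as tw:
        for i, band in enumerate(stack.bands):
            if dtype is not None and band.dtype != dtype:
                if np.issubdtype(np.dtype(dtype), np.integer):
                    band = np.rint(band)
                band = band.astype(dtype)
            tw.write(band, photometric="minisblack",
                     description=desc if i == 0 else None,
                     extratags=extratags if i == 0 else [])


def load_stack(path) -> BandStack:
    import json

    import tifffile

    with tifffile.TiffFile(path) as tif:
        bands = [page.asarray() for page in tif.pages]
        desc = tif.pages[0].tags.get("ImageDescription")
        parsed = json.loads(desc.value) if desc is not None else {}
    meta = dict(parsed.get("metadata", {}))
    band_ids = tuple(meta.pop("band_ids", [f"band{i}" for i in range(len(bands))]))
    res = tuple(meta.pop("resolution_m", [10] * len(bands)))
    return BandStack(bands=bands, band_ids=band_ids, resolution_m=res,
                     geotransform=tuple(parsed.get("geotransform",
                                                   IDENTITY_TRANSFORM)),
                     crs=parsed.get("crs"), metadata=meta)
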