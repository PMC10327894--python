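"""Minimal GeoTIFF reading/writing built on tifffile.

Stores the affine geotransform through the ModelPixelScale / ModelTiepoint
tags, the CRS through a minimal GeoKeyDirectory (EPSG code only), and any
per-band metadata (band ids, stretch parameters) as JSON in the
ImageDescription tag.  This intentionally covers only the subset of GeoTIFF
needed to round-trip rasters exported from standard GIS tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

MODEL_PIXEL_SCALE = 33550
MODEL_TIEPOINT = 33922
GEO_KEY_DIRECTORY = 34735

#: identity geotransform (GDAL order: x0, dx, rx, y0, ry, dy)
IDENTITY_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


@dataclass
class Raster:
    data: np.ndarray                       # (bands, H, W) or (H, W)
    geotransform: tuple = IDENTITY_TRANSFORM
    crs: str | None = None                 # e.g. "EPSG:32649"
    metadata: dict = field(default_factory=dict)

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]


def _epsg_code(crs: str | None) -> int | None:
    if crs and crs.upper().startswith("EPSG:"):
        return int(crs.split(":")[1])
    return None


def write_geotiff(path, data, geotransform=IDENTITY_TRANSFORM, crs=None,
                  metadata=None, dtype=None) -> None:
    data = np.asarray(data)
    if dtype is not None and data.dtype != dtype:
        if np.issubdtype(np.dtype(dtype), np.integer):
            data = np.rint(data)  # round half to even on integer export
        data = data.astype(dtype)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    x0, dx, rx, y0, ry, dy = geotransform
    extratags = [
        (MODEL_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    epsg = _epsg_code(crs)
    if epsg is not None:
        keys = (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, epsg)
        extratags.append((GEO_KEY_DIRECTORY, "H", len(keys), keys))
    desc = json.dumps({"geotransform": list(geotransform), "crs": crs,
                       "metadata": metadata or {}})
    kwargs = {"planarconfig": "separate"} if data.ndim == 3 else {}
    tifffile.imwrite(path, data, photometric="minisblack", description=desc,
                     extratags=extratags, **kwargs)


def read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        desc = page.tags.get("ImageDescription")
        geotransform, crs, metadata = IDENTITY_TRANSFORM, None, {}
        if desc is not None:
            try:
                parsed = json.loads(desc.value)
                geotransform = tuple(parsed.get("geotransform", IDENTITY_TRANSFORM))
                crs = parsed.get("crs")
                metadata = parsed.get("metadata", {})
            except (json.JSONDecodeError, AttributeError):
                pass
        if crs is None and GEO_KEY_DIRECTORY in page.tags:
            keys = page.tags[GEO_KEY_DIRECTORY].value
            for i in range(4, len(keys), 4):
                if keys[i] == 3072:
                    crs = f"EPSG:{keys[i + 3]}"
        if MODEL_PIXEL_SCALE in page.tags and MODEL_TIEPOINT in page.tags \
                and geotransform == IDENTITY_TRANSFORM:
            sx, sy, _ = page.tags[MODEL_PIXEL_SCALE].value[:3]
            tp = page.tags[MODEL_TIEPOINT].value
            geotransform = (tp[3], sx, 0.0, tp[4], 0.0, -sy)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    return Raster(data=data, geotransform=tuple(geotransform), crs=crs,
                  metadata=metadata)
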