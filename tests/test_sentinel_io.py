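"""Band screening, bilinear resampling, fusion, stretching, harmonization."""

import numpy as np
import pytest

from agrinet import sentinel_io as sio
from agrinet.sentinel_io import (BandStack, StretchParams, fuse, harmonize,
                                 linear_stretch, preprocess_stack,
                                 resample_to_10m, select_bands)


def make_raw(h10=48, w10=48, seed=0):
    """Synthetic 13-band stack at native 10/20/60 m resolutions."""
    rng = np.random.default_rng(seed)
    bands, ids, res = [], [], []
    for bid, r in sio.NATIVE_RESOLUTION.items():
        f = r // 10
        bands.append(rng.integers(0, 4000, (h10 // f, w10 // f)).astype(float))
        ids.append(bid)
        res.append(r)
    return BandStack(bands=bands, band_ids=ids, resolution_m=res,
                     geotransform=(600000.0, 10.0, 0, 3500000.0, 0, -10.0),
                     crs="EPSG:32649")


# -- band selection --------------------------------------------------------

def test_select_bands_screens_atmospheric_bands():
    sel = select_bands(make_raw())
    assert sel.band_ids == sio.CANONICAL_BANDS
    assert not set(sio.EXCLUDED_BANDS) & set(sel.band_ids)
    assert sel.n_bands == 10


def test_select_bands_identity_on_clean_stack():
    sel = select_bands(make_raw())
    again = select_bands(sel)
    assert again.band_ids == sel.band_ids
    for a, b in zip(again.bands, sel.bands):
        assert np.array_equal(a, b)


def test_select_bands_missing_band_named_in_error():
    raw = make_raw()
    idx = raw.band_ids.index("B11")
    broken = BandStack(bands=[b for i, b in enumerate(raw.bands) if i != idx],
                       band_ids=[b for i, b in enumerate(raw.band_ids) if i != idx],
                       resolution_m=[r for i, r in enumerate(raw.resolution_m)
                                     if i != idx])
    with pytest.raises(ValueError, match="B11"):
        select_bands(broken)


# -- bilinear resampling ---------------------------------------------------

def bilinear_oracle(band, factor):
    """Brute-force bilinear interpolation under the half-pixel-center
    convention, written independently of the implementation."""
    h, w = band.shape
    oh, ow = h * factor, w * factor
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            sy = (i + 0.5) * h / oh - 0.5
            sx = (j + 0.5) * w / ow - 0.5
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            fy, fx = sy - y0, sx - x0
            def at(y, x):
                return band[min(max(y, 0), h - 1), min(max(x, 0), w - 1)]
            out[i, j] = ((1 - fy) * (1 - fx) * at(y0, x0)
                         + (1 - fy) * fx * at(y0, x0 + 1)
                         + fy * (1 - fx) * at(y0 + 1, x0)
                         + fy * fx * at(y0 + 1, x0 + 1))
    return out


def test_resample_matches_bilinear_oracle():
    band = np.array([[0.0, 10.0], [20.0, 30.0]])
    assert np.allclose(resample_to_10m(band, 20), bilinear_oracle(band, 2))
    rng = np.random.default_rng(3)
    band = rng.uniform(0, 1000, (5, 7))
    assert np.allclose(resample_to_10m(band, 20), bilinear_oracle(band, 2))


def test_resample_constant_and_identity():
    const = np.full((4, 4), 7.0)
    up = resample_to_10m(const, 20)
    assert up.shape == (8, 8) and np.allclose(up, 7.0)
    band = np.arange(12.0).reshape(3, 4)
    assert resample_to_10m(band, 10) is band


def test_resample_preserves_minmax_envelope(rng):
    band = rng.uniform(0, 4000, (9, 6))
    up = resample_to_10m(band, 20)
    assert up.min() >= band.min() - 1e-9 and up.max() <= band.max() + 1e-9


def test_resample_rejects_unsupported_resolution():
    with pytest.raises(ValueError, match="60"):
        resample_to_10m(np.ones((4, 4)), 60)


# -- fusion ----------------------------------------------------------------

def test_fuse_builds_10_channel_stack():
    stack = fuse([np.ones((8, 8)) * i for i in range(10)])
    assert stack.n_bands == 10
    assert stack.as_array().shape == (10, 8, 8)
    assert all(r == 10 for r in stack.resolution_m)


def test_fuse_arity_and_shape_errors():
    with pytest.raises(ValueError, match="10 bands"):
        fuse([np.ones((8, 8))] * 9)
    bands = [np.ones((8, 8))] * 9 + [np.ones((4, 4))]
    with pytest.raises(ValueError, match="B12"):
        fuse(bands)


def test_preprocess_pipeline_shape_contract():
    raw = make_raw(h10=64, w10=48)
    fused = preprocess_stack(raw)
    assert fused.as_array().shape == (10, 64, 48)
    assert fused.band_ids == sio.CANONICAL_BANDS
    assert fused.geotransform == raw.geotransform and fused.crs == raw.crs


# -- linear stretch --------------------------------------------------------

def test_stretch_endpoints_and_midpoint():
    p = StretchParams(min_in=0, max_in=200, min_out=0, max_out=100)
    band = np.array([0.0, 200.0, 50.0, -10.0, 500.0])
    out = linear_stretch(band, p)
    assert out[0] == 0.0 and out[1] == 100.0       # endpoints map exactly
    assert out[2] == 25.0                          # direct evaluation
    assert out[3] == 0.0 and out[4] == 100.0       # clipped to output bounds


def test_stretch_to_own_range_is_identity(rng):
    band = rng.uniform(100, 900, (16, 16))
    p = StretchParams(min_in=band.min(), max_in=band.max(),
                      min_out=band.min(), max_out=band.max())
    assert np.allclose(linear_stretch(band, p), band)


def test_stretch_params_validation():
    with pytest.raises(ValueError):
        StretchParams(min_in=5, max_in=5, min_out=0, max_out=1)
    with pytest.raises(ValueError):
        StretchParams(min_in=0, max_in=1, min_out=0, max_out=1, clip_percent=0.5)


# -- harmonization ---------------------------------------------------------

def two_stacks(rng):
    ref = fuse([rng.uniform(0, 200, (8, 8)) for _ in range(10)])
    tgt = fuse([rng.uniform(100, 300, (8, 8)) for _ in range(10)])
    return ref, tgt


def test_harmonize_matches_reference_range(rng):
    ref, tgt = two_stacks(rng)
    out = harmonize(ref, tgt)
    for bid in out.band_ids:
        assert out.band(bid).min() == pytest.approx(ref.band(bid).min())
        assert out.band(bid).max() == pytest.approx(ref.band(bid).max())
    assert set(out.metadata["stretch_params"]) == set(out.band_ids)


def test_harmonize_identity_when_ranges_coincide(rng):
    ref, _ = two_stacks(rng)
    out = harmonize(ref, ref)
    for bid in out.band_ids:
        assert np.allclose(out.band(bid), ref.band(bid))


def test_harmonize_rejects_degenerate_reference(rng):
    ref, tgt = two_stacks(rng)
    ref.bands[3] = np.full((8, 8), 42.0)
    with pytest.raises(ValueError, match="B5"):
        harmonize(ref, tgt)


def test_harmonize_rejects_band_mismatch(rng):
    ref, tgt = two_stacks(rng)
    renamed = BandStack(bands=tgt.bands, band_ids=["X"] + list(tgt.band_ids[1:]),
                        resolution_m=tgt.resolution_m)
    with pytest.raises(ValueError, match="mismatch"):
        harmonize(ref, renamed)


# -- GeoTIFF round trip ----------------------------------------------------

def test_stack_geotiff_round_trip(tmp_path, rng):
    ref, tgt = two_stacks(rng)
    out = harmonize(ref, tgt)
    path = tmp_path / "stack.tif"
    sio.save_stack(path, out)
    back = sio.load_stack(path)
    assert back.band_ids == out.band_ids
    assert back.crs == out.crs
    assert np.allclose(back.geotransform, out.geotransform)
    assert np.allclose(back.as_array(), out.as_array())
    assert "stretch_params" in back.metadata
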