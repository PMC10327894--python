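"""Architecture contracts: shuffle units, channel shuffle, attention, ASPP,
and the full forward pass feature-scale contract."""

import itertools

import numpy as np
import pytest

from agrinet import nn
from agrinet.deep_agrinet import (ASPP, CBAM, ChannelAttention, DeepAgriNet,
                                  NetworkConfig, ShuffleUnitBasic,
                                  ShuffleUnitDown, SpatialAttention,
                                  channel_shuffle, channel_shuffle_permutation)
from agrinet.nn.tensor import Tensor
from conftest import small_network_config


def as_tensor(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


# -- channel shuffle -------------------------------------------------------

def test_channel_shuffle_known_permutation():
    x = np.zeros((1, 4, 2, 2), dtype=np.float32)
    for c in range(4):
        x[:, c] = c
    out = channel_shuffle(as_tensor(x), 2).data
    assert [int(out[0, c, 0, 0]) for c in range(4)] == [0, 2, 1, 3]


def test_channel_shuffle_groups_one_is_identity(rng):
    x = rng.normal(size=(2, 6, 3, 3)).astype(np.float32)
    assert np.array_equal(channel_shuffle(as_tensor(x), 1).data, x)


def test_channel_shuffle_inverse_composition(rng):
    x = rng.normal(size=(1, 8, 2, 2)).astype(np.float32)
    once = channel_shuffle(as_tensor(x), 2)
    back = channel_shuffle(once, 4)   # groups = C / 2 inverts
    assert np.array_equal(back.data, x)


@pytest.mark.parametrize("c,groups", [(c, g) for c in (2, 4, 6, 8)
                                      for g in (1, 2) if c % g == 0])
def test_channel_shuffle_is_bijection(c, groups):
    perm = channel_shuffle_permutation(c, groups)
    assert sorted(perm.tolist()) == list(range(c))
    # permutation matches the tensor operation
    x = np.zeros((1, c, 1, 1), dtype=np.float32)
    x[0, :, 0, 0] = np.arange(c)
    out = channel_shuffle(as_tensor(x), groups).data[0, :, 0, 0]
    assert np.array_equal(out.astype(int), perm)


def test_channel_shuffle_rejects_indivisible():
    with pytest.raises(ValueError):
        channel_shuffle(as_tensor(np.zeros((1, 5, 2, 2))), 2)


# -- shuffle units ---------------------------------------------------------

def test_basic_unit_preserves_shape(rng):
    unit = ShuffleUnitBasic(8, rng=rng).eval()
    out = unit(as_tensor(rng.normal(size=(2, 8, 6, 6))))
    assert out.shape == (2, 8, 6, 6)


def test_basic_unit_rejects_odd_channels():
    with pytest.raises(ValueError, match="even"):
        ShuffleUnitBasic(7)


def _make_identity(unit: ShuffleUnitBasic):
    """Set the transform branch to (approximately) the identity map."""
    half = unit.channels // 2
    for block in unit.branch:
        conv, bn = block[0], block[1]
        w = np.zeros_like(conv.weight.data)
        if conv.groups == half:       # depthwise: center tap 1
            w[:, 0, w.shape[2] // 2, w.shape[3] // 2] = 1.0
        else:                         # 1x1: identity matrix
            for c in range(half):
                w[c, c, 0, 0] = 1.0
        conv.weight.data = w
        bn._buffers["running_mean"][:] = 0.0
        bn._buffers["running_var"][:] = 1.0
        bn.weight.data[:] = 1.0
        bn.bias.data[:] = 0.0
    unit.eval()


def test_basic_unit_identity_weights_is_channel_permutation(rng):
    c = 8
    unit = ShuffleUnitBasic(c, rng=rng)
    _make_identity(unit)
    x = np.abs(rng.normal(size=(1, c, 4, 4))).astype(np.float32) + 0.1
    out = unit(as_tensor(x)).data
    expected_perm = channel_shuffle_permutation(c, 2)
    assert np.allclose(out, x[:, expected_perm], rtol=1e-4, atol=1e-4)


def test_down_unit_doubles_channels_and_halves_space(rng):
    unit = ShuffleUnitDown(24, 48, rng=rng).eval()
    assert unit(as_tensor(rng.normal(size=(1, 24, 16, 16)))).shape == (1, 48, 8, 8)
    # the stage-3 transition of the 1.0x encoder
    unit2 = ShuffleUnitDown(116, 232, rng=rng).eval()
    assert unit2(as_tensor(rng.normal(size=(1, 116, 8, 8)))).shape == (1, 232, 4, 4)


def test_down_unit_rejects_degenerate_spatial(rng):
    unit = ShuffleUnitDown(8, 16, rng=rng).eval()
    with pytest.raises(ValueError):
        unit(as_tensor(np.zeros((1, 8, 1, 1))))


# -- attention -------------------------------------------------------------

def test_channel_attention_constant_input_equals_double_mlp(rng):
    cam = ChannelAttention(8, 2, rng=rng)
    x = as_tensor(np.broadcast_to(
        rng.normal(size=(1, 8, 1, 1)), (1, 8, 5, 5)).copy())
    gate = cam(x).data.reshape(8)
    v = Tensor(x.data[:, :, 0, 0])
    expected = 1 / (1 + np.exp(-2 * cam._mlp(v).data.reshape(8)))
    assert np.allclose(gate, expected, rtol=1e-5)


def test_channel_attention_zero_mlp_gives_half(rng):
    cam = ChannelAttention(8, 2, rng=rng)
    cam.fc1.weight.data[:] = 0
    cam.fc2.weight.data[:] = 0
    cam.fc1.bias.data[:] = 0
    cam.fc2.bias.data[:] = 0
    gate = cam(as_tensor(rng.normal(size=(2, 8, 4, 4)))).data
    assert np.allclose(gate, 0.5)


def test_channel_attention_rejects_large_reduction():
    with pytest.raises(ValueError):
        ChannelAttention(8, 8)


def test_spatial_attention_single_channel_pools_to_input(rng):
    sam = SpatialAttention(rng=rng)
    sam.conv.weight.data[:] = 0
    sam.conv.weight.data[0, 0, 3, 3] = 1.0   # picks the channel-mean map
    sam.conv.bias.data[:] = 0
    x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
    out = sam(as_tensor(x)).data
    assert np.allclose(out, 1 / (1 + np.exp(-x)), rtol=1e-5)


def test_attention_maps_strictly_in_unit_interval(rng):
    cbam = CBAM(16, 4, rng=rng)
    maps = cbam.attention_maps(as_tensor(rng.normal(size=(2, 16, 8, 8))))
    for m in (maps.channel_map, maps.spatial_map):
        assert (m > 0).all() and (m < 1).all()
    assert maps.channel_map.shape == (2, 16, 1, 1)
    assert maps.spatial_map.shape == (2, 1, 8, 8)


def test_cbam_output_bounded_by_input(rng):
    cbam = CBAM(16, 4, rng=rng)
    x = rng.normal(size=(1, 16, 8, 8)).astype(np.float32)
    out = cbam(as_tensor(x)).data
    assert out.shape == x.shape
    assert (np.abs(out) <= np.abs(x) + 1e-6).all()


def test_cbam_zero_parameters_gates_at_quarter(rng):
    cbam = CBAM(8, 2, rng=rng)
    for p in cbam.parameters():
        p.data[:] = 0
    x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
    assert np.allclose(cbam(as_tensor(x)).data, 0.25 * x, rtol=1e-5)


# -- ASPP ------------------------------------------------------------------

def test_aspp_shape_and_constant_field(rng):
    aspp = ASPP(8, 16, (1, 2, 3), rng=rng).eval()
    out = aspp(as_tensor(rng.normal(size=(1, 8, 10, 10))))
    assert out.shape == (1, 16, 10, 10)
    const = aspp(as_tensor(np.full((1, 8, 12, 12), 2.0, dtype=np.float32))).data
    # away from the zero-padded border every branch is spatially constant
    inner = const[:, :, 3:-3, 3:-3]
    assert np.allclose(inner, inner[:, :, :1, :1], atol=1e-4)


def test_dilated_kernel_equals_zero_inflated_kernel(rng):
    from agrinet.nn import functional as F
    x = as_tensor(rng.normal(size=(1, 3, 9, 9)))
    w = as_tensor(rng.normal(size=(4, 3, 3, 3)))
    inflated = np.zeros((4, 3, 5, 5), dtype=np.float32)
    inflated[:, :, ::2, ::2] = w.data
    a = F.conv2d(x, w, padding=2, dilation=2).data
    b = F.conv2d(x, as_tensor(inflated), padding=2).data
    assert np.allclose(a, b, atol=1e-5)


# -- full network ----------------------------------------------------------

def test_forward_feature_scale_contract(small_model):
    x = np.random.default_rng(5).normal(size=(1, 10, 64, 64)).astype(np.float32)
    fb = small_model.features(x)
    assert fb.low.shape[2:] == (32, 32)
    assert fb.mid.shape[2:] == (16, 16)
    assert fb.deep.shape[2:] == (4, 4)
    scores = small_model(Tensor(x))
    assert scores.shape == (1, 3, 64, 64)


def test_forward_fully_convolutional(small_model):
    rng = np.random.default_rng(6)
    for size in (32, 80):
        x = rng.normal(size=(1, 10, size, size)).astype(np.float32)
        assert small_model.predict(x).shape == (1, size, size)


def test_forward_input_validation(small_model):
    with pytest.raises(ValueError, match="channels"):
        small_model.predict(np.zeros((1, 3, 64, 64), dtype=np.float32))
    with pytest.raises(ValueError, match="divisible"):
        small_model.predict(np.zeros((1, 10, 60, 60), dtype=np.float32))


def test_forward_batch_consistency(small_model):
    rng = np.random.default_rng(7)
    x = rng.normal(size=(3, 10, 32, 32)).astype(np.float32)
    batched = small_model.predict(x)
    single = np.concatenate([small_model.predict(x[i:i + 1]) for i in range(3)])
    assert np.array_equal(batched, single)


def test_forward_deterministic_in_eval(small_model):
    x = np.random.default_rng(8).normal(size=(1, 10, 32, 32)).astype(np.float32)
    a = small_model(Tensor(x)).data
    b = small_model(Tensor(x)).data
    assert np.array_equal(a, b)


def test_ablation_strictly_smaller():
    cfg = small_network_config()
    on = DeepAgriNet(cfg).num_parameters()
    off = DeepAgriNet(cfg.ablated()).num_parameters()
    assert off < on


def test_config_rejects_nonstandard_spatial_kernel():
    with pytest.raises(ValueError, match="7x7"):
        NetworkConfig(cbam_spatial_kernel=5)
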