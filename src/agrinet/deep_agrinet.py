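"""Lightweight attention-based encoder-decoder for 10-band crop segmentation.

The network couples a ShuffleNet v2 encoder (truncated at Stage3, output
stride 16) with an atrous-spatial-pyramid-pooling context head and a
DeepLab-v3+-style decoder augmented with a convolutional block attention
module (CBAM).  The input stem accepts the 10 fused Sentinel-2 bands; the
decoder taps the encoder at three scales:

* ``low``  — stem (Conv1) output, input/2 spatial scale, 24 channels
* ``mid``  — max-pool output, input/4 scale, 24 channels
* ``deep`` — Stage3 output, input/16 scale, 232 channels (1.0x width)

and restores full resolution through a 4x bilinear upsample, a 2x bilinear
upsample and a final stride-2 transpose convolution to per-pixel class
scores for {background, winter canola, winter wheat}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat, ensure_tensor, narrow, no_grad

#: ShuffleNet v2 stage widths (Conv1, Stage2, Stage3) per width multiplier.
STAGE_CHANNELS = {
    0.5: (24, 48, 96),
    1.0: (24, 116, 232),
    1.5: (24, 176, 352),
    2.0: (24, 244, 488),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Every architectural hyperparameter needed to rebuild the model.

    The decoder widths (``deep_refine_channels``, ``refine_channels_mid``,
    ``refine_channels_low``) and the channel-attention reduction ratio are
    the calibrated defaults recorded by the complexity profiler; see
    docs/methods.md for how they were chosen.
    """

    in_channels: int = 10
    num_classes: int = 3
    encoder_width_scale: float = 1.0
    stage_repeats: tuple = (4, 8)
    stage_out_channels: tuple | None = None
    aspp_dilations: tuple = (6, 12, 18)
    aspp_out_channels: int = 256
    deep_refine_channels: int = 240
    cbam_reduction: int = 8
    cbam_spatial_kernel: int = 7
    skip_reduce_channels_low: int = 48
    skip_reduce_channels_mid: int = 48
    refine_channels_mid: int = 184
    refine_channels_low: int = 244
    use_cbam: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.cbam_spatial_kernel != 7:
            raise ValueError("the spatial attention kernel is fixed at 7x7")
        if self.stage_out_channels is None:
            if self.encoder_width_scale not in STAGE_CHANNELS:
                raise ValueError(
                    f"no canonical stage widths for scale "
                    f"{self.encoder_width_scale}; pass stage_out_channels")
            object.__setattr__(self, "stage_out_channels",
                               STAGE_CHANNELS[self.encoder_width_scale])
        for name in ("in_channels", "num_classes", "aspp_out_channels",
                     "deep_refine_channels", "skip_reduce_channels_low",
                     "skip_reduce_channels_mid", "refine_channels_mid",
                     "refine_channels_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def ablated(self) -> "NetworkConfig":
        """The CBAM-off ablation, everything else unchanged."""
        return replace(self, use_cbam=False)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("stage_repeats", "stage_out_channels", "aspp_dilations"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("stage_repeats", "stage_out_channels", "aspp_dilations"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class FeatureBundle:
    """Encoder taps used by the decoder skip connections."""

    low: np.ndarray    # input/2 scale
    mid: np.ndarray    # input/4 scale
    deep: np.ndarray   # input/16 scale


@dataclass
class AttentionMaps:
    channel_map: np.ndarray  # (N, C, 1, 1), values in (0, 1)
    spatial_map: np.ndarray  # (N, 1, H, W), values in (0, 1)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def channel_shuffle(x, groups: int = 2) -> Tensor:
    """Reshape-to-(groups, C/groups)-then-transpose channel permutation."""
    x = ensure_tensor(x)
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channel count {c} not divisible by groups={groups}")
    out = x.reshape((n, groups, c // groups, h, w))
    out = nn.tensor.transpose(out, (0, 2, 1, 3, 4))
    return out.reshape((n, c, h, w))


def channel_shuffle_permutation(channels: int, groups: int = 2) -> np.ndarray:
    """Index permutation applied by :func:`channel_shuffle` (for analysis)."""
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


class ShuffleUnitBasic(nn.Module):
    """Basic ShuffleNet v2 unit: channel split, identity + 3-conv branch,
    concatenation and channel shuffle.  Shape preserving."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        if channels % 2:
            raise ValueError(f"basic shuffle unit needs even channels, got {channels}")
        half = channels // 2
        self.channels = channels
        self.branch = nn.Sequential(
            nn.ConvBNReLU(half, half, 1, rng=rng),
            nn.ConvBNReLU(half, half, 3, padding=1, groups=half, rng=rng,
                          activate=False),
            nn.ConvBNReLU(half, half, 1, rng=rng),
        )

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        half = self.channels // 2
        passive = narrow(x, 1, 0, half)
        active = narrow(x, 1, half, half)
        out = concat([passive, self.branch(active)], axis=1)
        return channel_shuffle(out, 2)

    def trace(self, hw):
        for name, sub in (("branch.0", self.branch[0]), ("branch.1", self.branch[1]),
                          ("branch.2", self.branch[2])):
            yield f"{name}.conv", sub[0], hw
            yield f"{name}.bn", sub[1], hw


class ShuffleUnitDown(nn.Module):
    """Spatial-downsampling unit: no split, both branches stride 2, the
    concatenation doubles channels: (C, H, W) -> (2C, H/2, W/2)."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        half = out_channels // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.branch_proj = nn.Sequential(
            nn.ConvBNReLU(in_channels, in_channels, 3, stride=2, padding=1,
                          groups=in_channels, rng=rng, activate=False),
            nn.ConvBNReLU(in_channels, half, 1, rng=rng),
        )
        self.branch_main = nn.Sequential(
            nn.ConvBNReLU(in_channels, half, 1, rng=rng),
            nn.ConvBNReLU(half, half, 3, stride=2, padding=1, groups=half,
                          rng=rng, activate=False),
            nn.ConvBNReLU(half, half, 1, rng=rng),
        )

    def forward(self, x):
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError("cannot halve a spatial dimension below 2 pixels")
        out = concat([self.branch_proj(x), self.branch_main(x)], axis=1)
        return channel_shuffle(out, 2)

    def trace(self, hw):
        out = (hw[0] // 2, hw[1] // 2)
        yield "branch_proj.0.conv", self.branch_proj[0][0], out
        yield "branch_proj.0.bn", self.branch_proj[0][1], out
        yield "branch_proj.1.conv", self.branch_proj[1][0], out
        yield "branch_proj.1.bn", self.branch_proj[1][1], out
        yield "branch_main.0.conv", self.branch_main[0][0], hw
        yield "branch_main.0.bn", self.branch_main[0][1], hw
        yield "branch_main.1.conv", self.branch_main[1][0], out
        yield "branch_main.1.bn", self.branch_main[1][1], out
        yield "branch_main.2.conv", self.branch_main[2][0], out
        yield "branch_main.2.bn", self.branch_main[2][1], out


class ChannelAttention(nn.Module):
    """Channel gate: sigma(MLP(AvgPool(F)) + MLP(MaxPool(F))), one shared
    two-layer MLP (C -> C/r -> C)."""

    def __init__(self, channels: int, reduction: int, rng=None):
        super().__init__()
        if reduction >= channels:
            raise ValueError(f"reduction {reduction} must be < channels {channels}")
        self.channels = channels
        self.reduction = reduction
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def _mlp(self, v):
        return self.fc2(nn.relu(self.fc1(v)))

    def forward(self, x):
        x = ensure_tensor(x)
        n, c = x.shape[0], x.shape[1]
        avg = F.global_avg_pool(x).reshape((n, c))
        mx = F.global_max_pool(x).reshape((n, c))
        gate = nn.sigmoid(self._mlp(avg) + self._mlp(mx))
        return gate.reshape((n, c, 1, 1))

    def trace(self, hw):
        yield "fc1", self.fc1, (1, 1)
        yield "fc2", self.fc2, (1, 1)


class SpatialAttention(nn.Module):
    """Spatial gate: sigma(f7x7([AvgPool_c(F); MaxPool_c(F)]))."""

    def __init__(self, kernel: int = 7, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def forward(self, x):
        x = ensure_tensor(x)
        avg = x.mean(axis=1, keepdims=True)
        mx = nn.tensor.reduce_max(x, axis=1, keepdims=True)
        return nn.sigmoid(self.conv(concat([avg, mx], axis=1)))

    def trace(self, hw):
        yield "conv", self.conv, hw


class CBAM(nn.Module):
    """Channel then spatial attention in series, each applied
    multiplicatively; shape preserving."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int = 7,
                 rng=None):
        super().__init__()
        self.cam = ChannelAttention(channels, reduction, rng=rng)
        self.sam = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x):
        x = ensure_tensor(x)
        refined = x * self.cam(x)
        return refined * self.sam(refined)

    def attention_maps(self, x) -> AttentionMaps:
        with no_grad():
            x = ensure_tensor(x)
            cmap = self.cam(x)
            smap = self.sam(x * cmap)
        return AttentionMaps(channel_map=cmap.data, spatial_map=smap.data)

    def trace(self, hw):
        for name, sub, shw in self.cam.trace(hw):
            yield f"cam.{name}", sub, shw
        for name, sub, shw in self.sam.trace(hw):
            yield f"sam.{name}", sub, shw


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: 1x1 conv, three dilated 3x3 convs and
    an image-pooling branch, concatenated and projected to ``out_channels``."""

    def __init__(self, in_channels: int, out_channels: int, dilations,
                 rng=None):
        super().__init__()
        self.dilations = tuple(dilations)
        self.b0 = nn.ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        for i, d in enumerate(self.dilations, start=1):
            self.register(f"b{i}", nn.ConvBNReLU(
                in_channels, out_channels, 3, padding=d, dilation=d, rng=rng))
        self.pool_conv = nn.ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        n_branches = 2 + len(self.dilations)
        self.project = nn.ConvBNReLU(n_branches * out_channels, out_channels,
                                     1, rng=rng)

    def forward(self, x):
        hw = (x.shape[2], x.shape[3])
        outs = [self.b0(x)]
        for i in range(1, len(self.dilations) + 1):
            outs.append(self._modules[f"b{i}"](x))
        pooled = self.pool_conv(F.global_avg_pool(x))
        outs.append(F.interpolate_bilinear(pooled, hw))
        return self.project(concat(outs, axis=1))

    def trace(self, hw):
        names = ["b0"] + [f"b{i}" for i in range(1, len(self.dilations) + 1)]
        for name in names:
            block = self._modules[name]
            yield f"{name}.conv", block[0], hw
            yield f"{name}.bn", block[1], hw
        yield "pool_conv.conv", self.pool_conv[0], (1, 1)
        yield "pool_conv.bn", self.pool_conv[1], (1, 1)
        yield "project.conv", self.project[0], hw
        yield "project.bn", self.project[1], hw


# ---------------------------------------------------------------------------
# the assembled network
# ---------------------------------------------------------------------------

class DeepAgriNet(nn.Module):
    """Full encoder-decoder; see the module docstring for the pipeline."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        cfg = config or NetworkConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.stage_out_channels

        self.stem = nn.ConvBNReLU(cfg.in_channels, c1, 3, stride=2, padding=1,
                                  rng=rng)
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        self.stage2 = self._make_stage(c1, c2, cfg.stage_repeats[0], rng)
        self.stage3 = self._make_stage(c2, c3, cfg.stage_repeats[1], rng)
        self.aspp = ASPP(c3, cfg.aspp_out_channels, cfg.aspp_dilations, rng=rng)
        self.deep_refine = nn.ConvBNReLU(cfg.aspp_out_channels,
                                         cfg.deep_refine_channels, 3,
                                         padding=1, rng=rng)
        if cfg.use_cbam:
            self.cbam = CBAM(cfg.deep_refine_channels, cfg.cbam_reduction,
                             cfg.cbam_spatial_kernel, rng=rng)
        self.reduce_mid = nn.ConvBNReLU(c1, cfg.skip_reduce_channels_mid, 1,
                                        rng=rng)
        self.refine_mid = nn.ConvBNReLU(
            cfg.deep_refine_channels + cfg.skip_reduce_channels_mid,
            cfg.refine_channels_mid, 3, padding=1, rng=rng)
        self.reduce_low = nn.ConvBNReLU(c1, cfg.skip_reduce_channels_low, 1,
                                        rng=rng)
        self.refine_low = nn.ConvBNReLU(
            cfg.refine_channels_mid + cfg.skip_reduce_channels_low,
            cfg.refine_channels_low, 3, padding=1, rng=rng)
        self.classifier = nn.ConvTranspose2d(cfg.refine_channels_low,
                                             cfg.num_classes, 4, 2, 1, rng=rng)

    @staticmethod
    def _make_stage(cin, cout, repeats, rng):
        units = [ShuffleUnitDown(cin, cout, rng=rng)]
        units += [ShuffleUnitBasic(cout, rng=rng) for _ in range(repeats - 1)]
        return nn.Sequential(*units)

    # -- forward ----------------------------------------------------------
    def _check_input(self, x):
        if x.ndim == 3:
            x = ensure_tensor(x).reshape((1,) + tuple(x.shape))
        x = ensure_tensor(x)
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {c}")
        if h % 16 or w % 16:
            raise ValueError(f"input sides must be divisible by 16, got {h}x{w}")
        return x

    def encode(self, x):
        x = self._check_input(x)
        low = self.stem(x)
        mid = self.maxpool(low)
        deep = self.stage3(self.stage2(mid))
        return low, mid, deep

    def forward(self, x) -> Tensor:
        low, mid, deep = self.encode(x)
        y = self.deep_refine(self.aspp(deep))
        y = F.interpolate_bilinear(y, (mid.shape[2], mid.shape[3]))
        if self.config.use_cbam:
            y = self.cbam(y)
        y = self.refine_mid(concat([y, self.reduce_mid(mid)], axis=1))
        y = F.interpolate_bilinear(y, (low.shape[2], low.shape[3]))
        y = self.refine_low(concat([y, self.reduce_low(low)], axis=1))
        return self.classifier(y)

    def features(self, x) -> FeatureBundle:
        with no_grad():
            low, mid, deep = self.encode(x)
        return FeatureBundle(low=low.data, mid=mid.data, deep=deep.data)

    def predict(self, x) -> np.ndarray:
        """Per-pixel argmax class labels, (N, H, W) uint8."""
        with no_grad():
            scores = self.forward(x)
        return scores.data.argmax(axis=1).astype(np.uint8)

    # -- symbolic trace for the complexity profiler -----------------------
    def layer_trace(self, input_hw: tuple):
        """Yield ``(name, leaf_module, out_hw)`` for every parameterised
        leaf layer, in forward order, with output sizes propagated
        symbolically from ``input_hw``."""
        h, w = input_hw
        if h % 16 or w % 16:
            raise ValueError("input sides must be divisible by 16")
        hw = self.stem[0].out_hw((h, w))
        yield "stem.conv", self.stem[0], hw
        yield "stem.bn", self.stem[1], hw
        hw = self.maxpool.out_hw(hw)
        for sname, stage in (("stage2", self.stage2), ("stage3", self.stage3)):
            for i, unit in enumerate(stage):
                for name, leaf, lhw in unit.trace(hw):
                    yield f"{sname}.{i}.{name}", leaf, lhw
                if isinstance(unit, ShuffleUnitDown):
                    hw = (hw[0] // 2, hw[1] // 2)
        deep_hw = hw
        for name, leaf, lhw in self.aspp.trace(deep_hw):
            yield f"aspp.{name}", leaf, lhw
        yield "deep_refine.conv", self.deep_refine[0], deep_hw
        yield "deep_refine.bn", self.deep_refine[1], deep_hw
        mid_hw = (h // 4, w // 4)
        if self.config.use_cbam:
            for name, leaf, lhw in self.cbam.trace(mid_hw):
                yield f"cbam.{name}", leaf, lhw
        yield "reduce_mid.conv", self.reduce_mid[0], mid_hw
        yield "reduce_mid.bn", self.reduce_mid[1], mid_hw
        yield "refine_mid.conv", self.refine_mid[0], mid_hw
        yield "refine_mid.bn", self.refine_mid[1], mid_hw
        low_hw = (h // 2, w // 2)
        yield "reduce_low.conv", self.reduce_low[0], low_hw
        yield "reduce_low.bn", self.reduce_low[1], low_hw
        yield "refine_low.conv", self.refine_low[0], low_hw
        yield "refine_low.bn", self.refine_low[1], low_hw
        yield "classifier", self.classifier, (h, w)


# functional views of the unit operations (convenience for analysis/tests)

def shuffle_unit_basic(x, cfg_or_unit, rng=None):
    unit = cfg_or_unit if isinstance(cfg_or_unit, ShuffleUnitBasic) \
        else ShuffleUnitBasic(ensure_tensor(x).shape[1],
                              rng=rng or np.random.default_rng(0))
    return unit(ensure_tensor(x))


def shuffle_unit_down(x, out_channels, rng=None):
    x = ensure_tensor(x)
    unit = ShuffleUnitDown(x.shape[1], out_channels,
                           rng=rng or np.random.default_rng(0))
    return unit(x)
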