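"""Parameter and FLOP accounting for the assembled network.

The headline totals follow the convolutional accounting convention

* ``parameter = K * K * C_in * C_out``  (per layer; grouped/depthwise
  convolutions use ``C_in / groups``),
* ``FLOPs = K * K * C_in * H_out * W_out * C_out``  (one multiply-accumulate
  counted once),

summed over every convolution, transpose convolution and fully-connected
layer (a fully-connected layer is the K=1, 1x1-output special case).  Bias
vectors and batch-normalisation affine parameters are itemized separately
and excluded from the headline totals; pooling, activations, normalisation
and elementwise work carry no FLOPs under this convention.  GFLOPs are the
total divided by 1e9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .nn.modules import BatchNorm2d, Conv2d, ConvTranspose2d, Linear, MaxPool2d


@dataclass
class LayerRecord:
    name: str
    kind: str
    kernel: int
    c_in: int
    c_out: int
    groups: int
    h_out: int
    w_out: int
    params: int        # headline (weight) parameters
    flops: int         # headline multiply-accumulates
    extra_params: int  # itemized bias / normalisation parameters


@dataclass
class ComplexityReport:
    model_name: str
    input_hw: tuple
    layers: list = field(default_factory=list)
    config: dict | None = None

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.layers)

    @property
    def total_extra_params(self) -> int:
        return sum(r.extra_params for r in self.layers)

    @property
    def total_flops(self) -> int:
        return sum(r.flops for r in self.layers)

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.layers])

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "input_hw": list(self.input_hw),
            "total_params": self.total_params,
            "params_millions": self.params_millions,
            "total_extra_params": self.total_extra_params,
            "total_flops": self.total_flops,
            "gflops": self.gflops,
            "config": self.config,
            "layers": [r.__dict__ for r in self.layers],
        }


def _record(name: str, layer, out_hw: tuple) -> LayerRecord | None:
    h, w = out_hw
    if isinstance(layer, Conv2d):
        k, g = layer.kernel_size, layer.groups
        cin, cout = layer.in_channels, layer.out_channels
        params = k * k * (cin // g) * cout
        flops = params * h * w
        extra = cout if layer.bias is not None else 0
        return LayerRecord(name, "conv", k, cin, cout, g, h, w, params, flops, extra)
    if isinstance(layer, ConvTranspose2d):
        k = layer.kernel_size
        cin, cout = layer.in_channels, layer.out_channels
        params = k * k * cin * cout
        flops = params * h * w
        extra = cout if layer.bias is not None else 0
        return LayerRecord(name, "conv_transpose", k, cin, cout, 1, h, w,
                           params, flops, extra)
    if isinstance(layer, Linear):
        cin, cout = layer.in_features, layer.out_features
        params = cin * cout
        extra = cout if layer.bias is not None else 0
        return LayerRecord(name, "linear", 1, cin, cout, 1, 1, 1, params,
                           params, extra)
    if isinstance(layer, BatchNorm2d):
        return LayerRecord(name, "batchnorm", 0, layer.num_features,
                           layer.num_features, 1, h, w, 0, 0,
                           2 * layer.num_features)
    if isinstance(layer, MaxPool2d):
        return None
    raise TypeError(f"unknown layer type {type(layer).__name__} at {name}")


def profile(model, input_hw=(512, 512), name: str | None = None) -> ComplexityReport:
    """Symbolically trace ``model`` at ``input_hw`` and tabulate Eq-style
    per-layer parameter and FLOP counts."""
    if not hasattr(model, "layer_trace"):
        raise TypeError("model does not expose a layer_trace; is it built?")
    h, w = input_hw
    if h % 16 or w % 16:
        raise ValueError(f"input sides must be divisible by 16, got {h}x{w}")
    report = ComplexityReport(
        model_name=name or type(model).__name__,
        input_hw=tuple(input_hw),
        config=model.config.to_dict() if hasattr(model, "config") else None)
    for lname, layer, out_hw in model.layer_trace(tuple(input_hw)):
        rec = _record(lname, layer, out_hw)
        if rec is not None:
            report.layers.append(rec)
    return report


def count_params(model) -> int:
    """Headline weight-parameter total (kernel x kernel x C_in x C_out)."""
    return profile(model, (512, 512)).total_params


def count_flops(model, input_hw=(512, 512)) -> int:
    return profile(model, input_hw).total_flops


def compare_configs(reports) -> pd.DataFrame:
    """Render a lightweightness comparison table from profiler reports."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    return pd.DataFrame([
        {"model": r.model_name, "params(M)": r.params_millions,
         "GFLOPs": round(r.gflops, 2), "input": f"{r.input_hw[0]}x{r.input_hw[1]}"}
        for r in reports])
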