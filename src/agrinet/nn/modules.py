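"""Layer modules: parameter containers with a torch-like Module tree."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, relu, sigmoid


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    def __init__(self):
        self._modules = {}
        self._params = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, module: "Module") -> "Module":
        setattr(self, name, module)
        return module

    # -- traversal --------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode / state -----------------------------------------------------
    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, mod in self.named_modules():
            for bname, buf in getattr(mod, "_buffers", {}).items():
                state[f"{name}.{bname}" if name else bname] = buf.copy()
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        buffers = {}
        for name, mod in self.named_modules():
            for bname in getattr(mod, "_buffers", {}):
                buffers[f"{name}.{bname}" if name else bname] = (mod, bname)
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data = value.astype(np.float32).copy()
            elif key in buffers:
                mod, bname = buffers[key]
                mod._buffers[bname] = value.astype(np.float32).copy()
            else:
                raise KeyError(f"unexpected key {key}")
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming_normal(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, dilation=1, groups=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        self.weight = Parameter(
            kaiming_normal((out_channels, in_channels // groups, k, k), fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)

    def out_hw(self, hw):
        return tuple(F._conv_out_size(s, self.kernel_size, self.stride,
                                      self.padding, self.dilation) for s in hw)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size=4, stride=2,
                 padding=1, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(kaiming_normal(
            (in_channels, out_channels, kernel_size, kernel_size), fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding)

    def out_hw(self, hw):
        return tuple(F.conv_transpose2d_out_size(
            s, self.kernel_size, self.stride, self.padding) for s in hw)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(kaiming_normal(
            (out_features, in_features), in_features, rng))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        from .tensor import matmul, transpose
        out = matmul(x, transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }

    def forward(self, x):
        from .tensor import reshape, power
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self._buffers["running_mean"] *= (1 - m)
            self._buffers["running_mean"] += m * mean.data.ravel()
            self._buffers["running_var"] *= (1 - m)
            self._buffers["running_var"] += m * unbiased
            inv = power(var + self.eps, -0.5)
            xhat = centered * inv
        else:
            rm = self._buffers["running_mean"].reshape(1, -1, 1, 1)
            rv = self._buffers["running_var"].reshape(1, -1, 1, 1)
            xhat = (x - rm) * (1.0 / np.sqrt(rv + self.eps))
        w = reshape(self.weight, (1, -1, 1, 1))
        b = reshape(self.bias, (1, -1, 1, 1))
        return xhat * w + b


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)

    def out_hw(self, hw):
        return tuple(F._conv_out_size(s, self.kernel_size, self.stride,
                                      self.padding, 1) for s in hw)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self._order = []
        for i, mod in enumerate(modules):
            self.register(str(i), mod)
            self._order.append(mod)

    def forward(self, x):
        for mod in self._order:
            x = mod(x)
        return x

    def __iter__(self):
        return iter(self._order)

    def __getitem__(self, i):
        return self._order[i]


class ConvBNReLU(Sequential):
    """3-op block used throughout the network; BN+ReLU follow every conv."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, dilation=1, groups=1, rng=None, activate=True):
        layers = [Conv2d(in_channels, out_channels, kernel_size, stride,
                         padding, dilation, groups, bias=False, rng=rng),
                  BatchNorm2d(out_channels)]
        if activate:
            layers.append(ReLU())
        super().__init__(*layers)
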