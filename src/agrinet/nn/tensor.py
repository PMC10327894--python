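"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations needed by the segmentation
network are provided; convolution and pooling live in
:mod:`agrinet.nn.functional`.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_f32(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float32)
    return arr


def unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free intermediate grads/graph to bound memory
                node._backward = None
                node._parents = ()
                node.grad = None

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -ensure_tensor(other))

    def __rsub__(self, other):
        return add(ensure_tensor(other), -self)

    def __truediv__(self, other):
        other = ensure_tensor(other)
        return mul(self, power(other, -1.0))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive operations --------------------------------------------------

def add(a, b) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = ensure_tensor(a)
    out_data = a.data ** np.float32(exponent)

    def backward(g):
        if a.requires_grad:
            a._accum(g * exponent * a.data ** np.float32(exponent - 1.0))

    return Tensor._result(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(unbroadcast(gb, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def relu(a) -> Tensor:
    a = ensure_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, np.float32(0.0))

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor._result(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = ensure_tensor(a)
    # clip to the float32 exp range; saturated values are exactly 0/1 anyway
    z = np.clip(a.data, -88.0, 88.0)
    out_data = 1.0 / (1.0 + np.exp(-z, dtype=np.float32))

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (a,), backward)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = ensure_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return Tensor._result(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = ensure_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis, keepdims), 1.0 / count)


def reduce_max(a, axis, keepdims=False) -> Tensor:
    """Max over ``axis``; gradient flows to (all) argmax positions equally split."""
    a = ensure_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data)

    def backward(g):
        if not a.requires_grad:
            return
        if not keepdims:
            g = np.expand_dims(g, axis) if not isinstance(axis, tuple) else np.reshape(
                g, out_data.shape)
        counts = mask.sum(axis=axis, keepdims=True)
        a._accum(mask * (g / counts))

    res = out_data if keepdims else np.squeeze(out_data, axis=axis)
    return Tensor._result(res, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = ensure_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return Tensor._result(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = ensure_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(np.transpose(g, inv))

    return Tensor._result(out_data, (a,), backward)


def flip(a, axes) -> Tensor:
    a = ensure_tensor(a)
    out_data = np.flip(a.data, axes)

    def backward(g):
        if a.requires_grad:
            a._accum(np.flip(g, axes).copy())

    return Tensor._result(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [ensure_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis."""
    a = ensure_tensor(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

    return Tensor._result(out_data, (a,), backward)


def pad2d(a, pad: tuple) -> Tensor:
    """Zero-pad the two trailing axes of an NCHW tensor: pad=(top,bottom,left,right)."""
    a = ensure_tensor(a)
    t, b, l, r = pad
    out_data = np.pad(a.data, ((0, 0), (0, 0), (t, b), (l, r)))

    def backward(g):
        if a.requires_grad:
            h, w = a.data.shape[2], a.data.shape[3]
            a._accum(g[:, :, t:t + h, l:l + w])

    return Tensor._result(out_data, (a,), backward)


def zero_insert2d(a, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between spatial samples (transpose-conv helper)."""
    a = ensure_tensor(a)
    if stride == 1:
        return a
    n, c, h, w = a.data.shape
    out_data = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1),
                        dtype=np.float32)
    out_data[:, :, ::stride, ::stride] = a.data

    def backward(g):
        if a.requires_grad:
            a._accum(g[:, :, ::stride, ::stride])

    return Tensor._result(out_data, (a,), backward)
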