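"""Convolution, pooling, resampling and loss primitives.

Convolutions are evaluated as a sum of K*K shifted 1x1 products, each a
single BLAS matmul over the channel dimension.  This keeps peak memory at
one feature map per kernel tap (no im2col buffer) and is the fastest pure
numpy strategy for the small kernels used here.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, ensure_tensor


def _conv_out_size(size: int, k: int, stride: int, pad: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def _conv2d_forward(x, w, stride, pad, dilation, groups):
    """x: (N,C,H,W); w: (Cout, Cin/groups, kh, kw) -> (N,Cout,Ho,Wo)."""
    n, c, h, wd = x.shape
    cout, cg, kh, kw = w.shape
    sh = sw = stride
    dh = dw = dilation
    ho = _conv_out_size(h, kh, sh, pad, dh)
    wo = _conv_out_size(wd, kw, sw, pad, dw)
    if ho <= 0 or wo <= 0:
        raise ValueError(f"conv output would be empty for input {h}x{wd}")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    g = groups
    wg = w.reshape(g, cout // g, cg, kh, kw)
    out = np.zeros((n, g, cout // g, ho * wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            i0, j0 = ki * dh, kj * dw
            xs = xp[:, :, i0:i0 + (ho - 1) * sh + 1:sh, j0:j0 + (wo - 1) * sw + 1:sw]
            xs = np.ascontiguousarray(xs).reshape(n, g, cg, ho * wo)
            out += wg[:, :, :, ki, kj] @ xs
    return out.reshape(n, cout, ho, wo), (ho, wo)


def _conv2d_backward(x, w, gout, stride, pad, dilation, groups,
                     need_gx: bool, need_gw: bool):
    n, c, h, wd = x.shape
    cout, cg, kh, kw = w.shape
    ho, wo = gout.shape[2], gout.shape[3]
    sh = sw = stride
    dh = dw = dilation
    g = groups
    wg = w.reshape(g, cout // g, cg, kh, kw)
    go = gout.reshape(n, g, cout // g, ho * wo)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    gxp = np.zeros_like(xp) if need_gx else None
    gw = np.zeros_like(wg) if need_gw else None
    for ki in range(kh):
        for kj in range(kw):
            i0, j0 = ki * dh, kj * dw
            rows = slice(i0, i0 + (ho - 1) * sh + 1, sh)
            cols = slice(j0, j0 + (wo - 1) * sw + 1, sw)
            if need_gw:
                xs = np.ascontiguousarray(xp[:, :, rows, cols]).reshape(n, g, cg, ho * wo)
                gw[:, :, :, ki, kj] += (go @ xs.transpose(0, 1, 3, 2)).sum(axis=0)
            if need_gx:
                contrib = wg[:, :, :, ki, kj].transpose(0, 2, 1) @ go
                gxp[:, :, rows, cols] += contrib.reshape(n, c, ho, wo)
    gx = None
    if need_gx:
        gx = gxp[:, :, pad:pad + h, pad:pad + wd] if pad else gxp
    return gx, (gw.reshape(w.shape) if need_gw else None)


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    x, weight = ensure_tensor(x), ensure_tensor(weight)
    if x.data.ndim != 4:
        raise ValueError("conv2d expects NCHW input")
    if x.data.shape[1] != weight.data.shape[1] * groups:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, weight expects "
            f"{weight.data.shape[1] * groups}")
    out_data, _ = _conv2d_forward(x.data, weight.data, stride, padding,
                                  dilation, groups)
    if bias is not None:
        bias = ensure_tensor(bias)
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)

    def backward(g):
        gx, gw = _conv2d_backward(x.data, weight.data, g, stride, padding,
                                  dilation, groups, x.requires_grad,
                                  weight.requires_grad)
        if x.requires_grad:
            x._accum(gx)
        if weight.requires_grad:
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._result(out_data, parents, backward)


def conv_transpose2d(x, weight, bias=None, stride: int = 2,
                     padding: int = 1) -> Tensor:
    """Transpose convolution; ``weight`` has shape (Cin, Cout, k, k).

    Implemented as zero insertion followed by an ordinary convolution with
    the spatially flipped, axis-swapped kernel, which is the textbook
    equivalence and reuses the conv2d gradient machinery.
    """
    from .tensor import flip, transpose, zero_insert2d, pad2d
    x, weight = ensure_tensor(x), ensure_tensor(weight)
    k = weight.data.shape[2]
    if x.data.shape[1] != weight.data.shape[0]:
        raise ValueError(
            f"conv_transpose2d: input has {x.data.shape[1]} channels, weight "
            f"expects {weight.data.shape[0]}")
    up = zero_insert2d(x, stride)
    margin = k - 1 - padding
    if margin < 0:
        raise ValueError("padding larger than kernel-1 is not supported")
    up = pad2d(up, (margin, margin, margin, margin))
    w_conv = transpose(flip(weight, (2, 3)), (1, 0, 2, 3))
    return conv2d(up, w_conv, bias=bias, stride=1, padding=0)


def conv_transpose2d_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size - 1) * stride - 2 * pad + k


def max_pool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = ensure_tensor(x)
    n, c, h, w = x.data.shape
    ho = _conv_out_size(h, kernel, stride, padding, 1)
    wo = _conv_out_size(w, kernel, stride, padding, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    out_data = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
    arg = np.zeros((n, c, ho, wo), dtype=np.int64)
    hp = xp.shape[2]
    wp = xp.shape[3]
    for ki in range(kernel):
        for kj in range(kernel):
            xs = xp[:, :, ki:ki + (ho - 1) * stride + 1:stride,
                    kj:kj + (wo - 1) * stride + 1:stride]
            flat = (np.arange(ho)[:, None] * stride + ki) * wp \
                + (np.arange(wo)[None, :] * stride + kj)
            better = xs > out_data
            out_data = np.where(better, xs, out_data)
            arg = np.where(better, flat[None, None], arg)

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, hp * wp), dtype=np.float32)
        nc_idx = np.repeat(np.arange(n * c), ho * wo)
        np.add.at(gxp.reshape(n * c, hp * wp), (nc_idx, arg.ravel()), g.ravel())
        gxp = gxp.reshape(n, c, hp, wp)
        x._accum(gxp[:, :, padding:padding + h, padding:padding + w])

    return Tensor._result(out_data, (x,), backward)


# -- bilinear resampling ---------------------------------------------------

def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation operator (n_out x n_in).

    Uses the half-pixel-center alignment convention: output sample ``i``
    maps to source coordinate ``(i + 0.5) * n_in / n_out - 0.5``; edge
    samples clamp to the border value.
    """
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        mat[i, lo_c] += 1.0 - frac
        mat[i, hi_c] += frac
    return mat


def interpolate_bilinear(x, out_hw: tuple) -> Tensor:
    """Resample NCHW tensor to ``out_hw`` with half-pixel-center bilinear."""
    x = ensure_tensor(x)
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    rmat = bilinear_matrix(h, oh)
    cmat = bilinear_matrix(w, ow)
    out_data = np.einsum("oi,nciw,pw->ncop", rmat, x.data, cmat, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("oi,ncop,pw->nciw", rmat, g, cmat, optimize=True))

    return Tensor._result(out_data.astype(np.float32), (x,), backward)


def global_avg_pool(x) -> Tensor:
    from .tensor import reduce_mean
    return reduce_mean(x, axis=(2, 3), keepdims=True)


def global_max_pool(x) -> Tensor:
    from .tensor import reduce_max
    return reduce_max(x, axis=(2, 3), keepdims=True)


# -- loss ------------------------------------------------------------------

def softmax_cross_entropy(scores, target) -> Tensor:
    """Mean per-pixel multi-class cross-entropy.

    ``scores``: (N, C, H, W) raw class scores; ``target``: (N, H, W) integer
    labels in [0, C).  Softmax over the class axis, then the mean over all
    pixels of -log p(true class).
    """
    scores = ensure_tensor(scores)
    target = np.asarray(target)
    n, c, h, w = scores.data.shape
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} does not match scores")
    if target.min() < 0 or target.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    z = scores.data - scores.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    prob = ez / ez.sum(axis=1, keepdims=True)
    npix = n * h * w
    ni, hi, wi = np.ogrid[:n, :h, :w]
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = -logp[ni, target, hi, wi].sum() / npix

    def backward(g):
        if scores.requires_grad:
            grad = prob.copy()
            grad[ni, target, hi, wi] -= 1.0
            scores._accum(grad * (float(g) / npix))

    return Tensor._result(np.float32(loss), (scores,), backward)
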