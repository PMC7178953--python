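"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation network needs: dilated
2-D convolution, stride-2 transposed convolution, batch normalization,
2x2 max pooling, bilinear upsampling, channel concatenation, ReLU/sigmoid,
and the scalar arithmetic required by the soft-Dice objective.  Tensors
carry float data of whatever dtype they are built from (float32 in the
network, float64 in numerical tests); gradients match the data dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "batch_norm2d",
    "max_pool2x2",
    "upsample_bilinear",
    "relu",
    "sigmoid",
]


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-propagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- scalar/elementwise arithmetic ------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _op(self.data + other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g, self.shape))
            _acc(other, _unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _op(self.data * other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g * other.data, self.shape))
            _acc(other, _unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _op(self.data / other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g / other.data, self.shape))
            _acc(other, _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        out._backward = bwd
        return out

    def sum(self):
        out = _op(np.asarray(self.data.sum()), (self,))

        def bwd(g):
            _acc(self, np.broadcast_to(g, self.shape))

        out._backward = bwd
        return out


def _as_tensor(x, dtype):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _op(data, parents):
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad or p._parents for p in out._parents)
    return out


def _acc(t, g):
    # leaves without requires_grad still accumulate if they are interior nodes
    if t.requires_grad or t._parents:
        t._accumulate(g)


def _unbroadcast(g, shape):
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- activations -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _op(np.maximum(x.data, 0), (x,))

    def bwd(g):
        _acc(x, g * (x.data > 0))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    s = s.astype(x.dtype)
    out = _op(s, (x,))

    def bwd(g):
        _acc(x, g * s * (1 - s))

    out._backward = bwd
    return out


# -- structural ops --------------------------------------------------------

def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _op(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _acc(t, piece)

    out._backward = bwd
    return out


# -- convolution -----------------------------------------------------------

def _im2col(xp, k, dilation, out_h, out_w):
    """Sliding 3x3 (or kxk) windows of a padded NCHW array, stride 1."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # v: (N, C, Hp-ke+1, Wp-ke+1, k, k) after subsampling taps by dilation
    if dilation > 1:
        ke = dilation * (k - 1) + 1
        v = np.lib.stride_tricks.sliding_window_view(xp, (ke, ke), axis=(2, 3))
        v = v[..., ::dilation, ::dilation]
    return v[:, :, :out_h, :out_w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-resolution stride-1 convolution with zero padding r*l per axis.

    x: (N, C, H, W); w: (Co, C, k, k) with odd k.  With dilation l the taps
    are spaced l pixels apart, so the receptive field is (2*r*l + 1) per axis
    while the parameter count is independent of l.
    """
    if dilation < 1:
        raise ValueError(f"dilation factor must be >= 1, got {dilation}")
    k = w.shape[-1]
    if k % 2 != 1 or w.shape[-2] != k:
        raise ValueError("kernel must be square with odd extent")
    r = k // 2
    pad = r * dilation
    N, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, dilation, H, W)  # (N, C, H, W, k, k)
    # true convolution: taps applied through the spatially flipped kernel
    wf = w.data[:, :, ::-1, ::-1]
    y = np.tensordot(cols, wf, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,Co)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if b is not None:
        y += b.data[None, :, None, None]
    out = _op(y.astype(x.dtype, copy=False), (x, w) + ((b,) if b is not None else ()))

    def bwd(g):
        # weight gradient (flip back to the unflipped parameter layout)
        gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3]))  # (Co, C, k, k)
        _acc(w, np.ascontiguousarray(gw[:, :, ::-1, ::-1]).astype(w.dtype, copy=False))
        if b is not None:
            _acc(b, g.sum(axis=(0, 2, 3)).astype(b.dtype, copy=False))
        # input gradient: scatter g*w back through each tap
        gxp = np.zeros_like(xp)
        gcols = np.tensordot(g, wf, axes=([1], [0]))  # (N, H, W, C, k, k)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i * dilation:i * dilation + H,
                    j * dilation:j * dilation + W] += \
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if pad:
            gxp = gxp[:, :, pad:-pad, pad:-pad]
        _acc(x, gxp)

    out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3 transposed convolution with stride 2 that exactly doubles H and W.

    w: (C_in, C_out, 3, 3).  Convention: input pixel (h, w) scatters its
    kernel onto output positions (2h + i - 1, 2w + j - 1); equivalent to
    padding=1 with output_padding=1.
    """
    N, C, H, W = x.shape
    Co = w.shape[1]
    prod = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N, H, W, Co, 3, 3)
    ypad = np.zeros((N, Co, 2 * H + 2, 2 * W + 2), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            ypad[:, :, i:i + 2 * H:2, j:j + 2 * W:2] += \
                prod[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    y = np.ascontiguousarray(ypad[:, :, 1:1 + 2 * H, 1:1 + 2 * W])
    if b is not None:
        y += b.data[None, :, None, None]
    out = _op(y, (x, w) + ((b,) if b is not None else ()))

    def bwd(g):
        gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for i in range(3):
            for j in range(3):
                patch = gp[:, :, i:i + 2 * H:2, j:j + 2 * W:2]  # (N, Co, H, W)
                gx += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1])
                                   ).transpose(0, 3, 1, 2)
                gw[:, :, i, j] = np.tensordot(x.data, patch,
                                              axes=([0, 2, 3], [0, 2, 3]))
        _acc(x, gx)
        _acc(w, gw)
        if b is not None:
            _acc(b, g.sum(axis=(0, 2, 3)).astype(b.dtype, copy=False))

    out._backward = bwd
    return out


# -- normalization and pooling --------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.9,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization on NCHW.

    In training mode the batch statistics are used and the running buffers
    (plain arrays, updated in place) track them with the given momentum; in
    inference mode the running statistics are used.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mean
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = _op(y.astype(x.dtype, copy=False), (x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        _acc(gamma, (g * xhat).sum(axis=(0, 2, 3)).astype(gamma.dtype, copy=False))
        _acc(beta, g.sum(axis=(0, 2, 3)).astype(beta.dtype, copy=False))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - s1 / m - xhat * s2 / m) * inv[None, :, None, None]
        else:
            gx = gxhat * inv[None, :, None, None]
        _acc(x, gx.astype(x.dtype, copy=False))

    out._backward = bwd
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; requires even spatial dims."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = _op(np.ascontiguousarray(y), (x,))

    def bwd(g):
        gr = np.zeros((N, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _acc(x, gr.reshape(N, C, H, W))

    out._backward = bwd
    return out


def _bilinear_weights(n_in, factor):
    """Half-pixel-centre source indices and weights for integer upscaling."""
    o = np.arange(n_in * factor)
    src = (o + 0.5) / factor - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0)
    w1[src < 0] = 0.0
    w1[src > n_in - 1] = 0.0
    return i0, i1, w1


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel convention)."""
    if factor == 1:
        return x
    N, C, H, W = x.shape
    r0, r1, wr = _bilinear_weights(H, factor)
    c0, c1, wc = _bilinear_weights(W, factor)
    wr_ = wr[None, None, :, None].astype(x.dtype)
    wc_ = wc[None, None, None, :].astype(x.dtype)
    rows = x.data[:, :, r0, :] * (1 - wr_) + x.data[:, :, r1, :] * wr_
    y = rows[:, :, :, c0] * (1 - wc_) + rows[:, :, :, c1] * wc_
    out = _op(y, (x,))

    def bwd(g):
        # undo the column interpolation, then the row interpolation
        grows = np.zeros((N, C, H * factor, W), dtype=g.dtype)
        np.add.at(grows.transpose(3, 0, 1, 2), c0, (g * (1 - wc_)).transpose(3, 0, 1, 2))
        np.add.at(grows.transpose(3, 0, 1, 2), c1, (g * wc_).transpose(3, 0, 1, 2))
        gx = np.zeros((N, C, H, W), dtype=g.dtype)
        np.add.at(gx.transpose(2, 0, 1, 3), r0,
                  (grows * (1 - wr)[None, None, :, None]).transpose(2, 0, 1, 3))
        np.add.at(gx.transpose(2, 0, 1, 3), r1,
                  (grows * wr[None, None, :, None]).transpose(2, 0, 1, 3))
        _acc(x, gx.astype(x.dtype, copy=False))

    out._backward = bwd
    return out
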