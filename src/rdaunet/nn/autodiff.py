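"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine sized for 2D convolutional encoder–decoder
networks: tensors wrap float64 ndarrays, every operation records a backward
closure, and :meth:`Tensor.backward` walks the tape in reverse topological
order.  Only the operations the segmentation network needs are provided
(convolution, transposed convolution, pooling, batch normalisation,
elementwise arithmetic, channel concatenation and the two activations).

Convolutions use an im2col formulation so the inner loop is a single BLAS
matmul; the gradient w.r.t. the input of a stride-1 'same' convolution is
itself a convolution with the spatially flipped, channel-transposed kernel,
which keeps the backward pass on the same fast path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "mul", "relu", "sigmoid", "concat", "tensor_sum",
    "conv2d", "conv_transpose2d_2x2", "maxpool2d_2x2",
    "batchnorm2d", "bce_loss", "dice_loss", "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode).

    Inside the context every operation returns a detached tensor, so large
    intermediates (notably im2col buffers) are freed as soon as the forward
    pass moves on.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (5-level U-Net)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data, parents, backward):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- elementwise

def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum with numpy broadcasting (e.g. (N,C,H,W) + (1,C,1,1))."""
    y = a.data + b.data

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(y, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise product with broadcasting (attention gating path)."""
    y = a.data * b.data

    def bwd(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(y, (a, b), bwd)


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] > 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def tensor_sum(x: Tensor) -> Tensor:
    """Sum all elements to a scalar (loss plumbing)."""
    y = x.data.sum()

    def bwd(g):
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _node(np.float64(y), (x,), bwd)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)

    def bwd(g):
        x._accumulate(g * (x.data > 0))

    return _node(y, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g):
        x._accumulate(g * y * (1.0 - y))

    return _node(y, (x,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate along `axis` (channel axis 1 for dense blocks / skips)."""
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(gpart)

    return _node(y, tuple(tensors), bwd)


# --------------------------------------------------------------- convolution

def _im2col(x, kh, kw, pad):
    """Unfold x (N,C,H,W) into (N*H'*W', C*kh*kw) patch rows, stride 1."""
    n, c = x.shape[:2]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,H',W',kh,kw
    hp, wp = win.shape[2], win.shape[3]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hp * wp, c * kh * kw), hp, wp


def _im2col_matmul(x, w, pad):
    """Correlate x (N,C,H,W) with w (O,C,kh,kw), stride 1, zero padding `pad`."""
    n = x.shape[0]
    o, c, kh, kw = w.shape
    cols, hp, wp = _im2col(x, kh, kw, pad)
    y = cols @ w.reshape(o, c * kh * kw).T
    return y.reshape(n, hp, wp, o).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int | None = None) -> Tensor:
    """Stride-1 2D convolution, 'same' padding by default for odd kernels.

    weight: (out_channels, in_channels, kh, kw); bias: (out_channels,).
    """
    o, c, kh, kw = weight.data.shape
    pad = (kh - 1) // 2 if padding is None else padding
    y, _ = _im2col_matmul(x.data, weight.data, pad)
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        n, _, hp, wp = g.shape
        gm = g.transpose(0, 2, 3, 1).reshape(n * hp * wp, o)
        # im2col is recomputed here rather than cached at forward time:
        # caching it would pin one large buffer per conv on the tape
        cols, _, _ = _im2col(x.data, kh, kw, pad)
        gw = (gm.T @ cols).reshape(weight.data.shape)
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        # dL/dx = g (*) rot180(W) with in/out channels swapped
        wt = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gx, _ = _im2col_matmul(g, wt, kh - 1 - pad)
        x._accumulate(gx)

    return _node(y, parents, bwd)


def conv_transpose2d_2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (exact 2x upsampling).

    weight: (in_channels, out_channels, 2, 2).  Because kernel size equals
    stride the output patches do not overlap, so forward and backward are
    plain einsums.
    """
    n, c, h, w = x.shape
    _, o, _, _ = weight.data.shape
    y = np.einsum("nchw,coab->nohawb", x.data, weight.data, optimize=True)
    y = y.reshape(n, o, 2 * h, 2 * w)
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gp = g.reshape(n, o, h, 2, w, 2)
        x._accumulate(np.einsum("nohawb,coab->nchw", gp, weight.data, optimize=True))
        weight._accumulate(np.einsum("nohawb,nchw->coab", gp, x.data, optimize=True))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return _node(y, parents, bwd)


def maxpool2d_2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d_2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # break ties: keep only the first max in each window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)

    def bwd(g):
        gx = mask * g[:, :, :, None, :, None]
        x._accumulate(gx.reshape(n, c, h, w))

    return _node(y, (x,), bwd)


# ----------------------------------------------------------- batch-norm, loss

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N,H,W) per channel.

    `running_mean`/`running_var` are plain ndarrays updated in place during
    training and used verbatim in evaluation mode.
    """
    c = x.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for running
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bwd(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gxhat = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - s1 / m - xhat * s2 / m) * inv_std.reshape(1, c, 1, 1)
        else:
            gx = gxhat * inv_std.reshape(1, c, 1, 1)
        x._accumulate(gx)

    return _node(y, (x, gamma, beta), bwd)


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy between a probability map and a {0,1} target.

    Probabilities are clipped to [eps, 1-eps] before the log, the standard
    guard for sigmoid-output networks trained on probabilities.
    """
    t = np.asarray(target, dtype=np.float64)
    p = np.clip(prob.data, eps, 1.0 - eps)
    y = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()

    def bwd(g):
        inside = (prob.data > eps) & (prob.data < 1.0 - eps)
        gp = g * (p - t) / (p * (1.0 - p)) / t.size
        prob._accumulate(np.where(inside, gp, 0.0))

    return _node(np.float64(y), (prob,), bwd)


def dice_loss(prob: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss: 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s)."""
    t = np.asarray(target, dtype=np.float64)
    inter = (prob.data * t).sum()
    denom = prob.data.sum() + t.sum() + smooth
    y = 1.0 - (2.0 * inter + smooth) / denom

    def bwd(g):
        gp = g * (-(2.0 * t * denom - (2.0 * inter + smooth)) / denom ** 2)
        prob._accumulate(gp)

    return _node(np.float64(y), (prob,), bwd)
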