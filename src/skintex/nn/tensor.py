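"""Minimal reverse-mode autodiff on NumPy arrays.

Implements exactly the operations the segmentation networks need — 2-D
convolution, batch normalization, 2x2 max pooling, 2x bilinear upsampling,
channel pooling, concatenation, elementwise arithmetic and the usual
activations — each with a hand-written vectorized backward pass. Gradients
are checked against numerical differentiation in the test suite.

Convolutions use stride 1 with symmetric zero padding; the kernel loop runs
over the (small) kernel footprint while everything else is batched BLAS
matmuls, which keeps memory flat and throughput acceptable on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d_s2", "maxpool2x2",
           "upsample_bilinear2x", "channel_max", "channel_mean", "mse_loss"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "parents", "grad_fn")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = tuple(parents)
        self.grad_fn = grad_fn  # grad_out -> tuple of parent grads (or None)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------ backward

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node.grad_fn is None or node.grad is None:
                continue
            for parent, pgrad in zip(node.parents, node.grad_fn(node.grad)):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # ---------------------------------------------------------- arithmetic

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def grad_fn(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor(out_data, (self, other), grad_fn)

    def __sub__(self, other: "Tensor") -> "Tensor":
        out_data = self.data - other.data

        def grad_fn(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(-g, other.data.shape))

        return Tensor(out_data, (self, other), grad_fn)

    def __mul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data * other.data

        def grad_fn(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, (self, other), grad_fn)

    def scale(self, s: float) -> "Tensor":
        return Tensor(self.data * s, (self,), lambda g: (g * s,))

    def mean(self) -> "Tensor":
        n = self.data.size

        def grad_fn(g):
            return (np.broadcast_to(g / n, self.data.shape).astype(self.data.dtype),)

        return Tensor(np.asarray(self.data.mean()), (self,), grad_fn)

    # --------------------------------------------------------- activations

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def grad_fn(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor(out_data, (self,), grad_fn)


# ------------------------------------------------------------- structural


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, tuple(tensors), grad_fn)


# ----------------------------------------------------------- convolutions


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with zero padding.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    n, c, h, wdt = x.data.shape
    o, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho, wo = h + 2 * p - kh + 1, wdt + 2 * p - kw + 1
    # im2col: one large GEMM instead of a loop of small ones
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)).reshape(
        c * kh * kw, n * ho * wo
    )
    w2 = w.data.reshape(o, c * kh * kw)
    out = (w2 @ cols).reshape(o, n, ho, wo).transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)
    out = np.ascontiguousarray(out)

    def grad_fn(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, n * ho * wo)
        gw = (g2 @ cols.T).reshape(w.data.shape)
        gcols = (w2.T @ g2).reshape(c, kh, kw, n, ho, wo)
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                gxp[:, :, di:di + ho, dj:dj + wo] += gcols[:, di, dj].transpose(
                    1, 0, 2, 3
                )
        gx = gxp[:, :, p:p + h, p:p + wdt] if p else gxp
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, grad_fn)


def conv_transpose2d_s2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2, stride-2 transposed convolution (learned upsampling).

    x: (N, C, H, W); w: (C, O, 2, 2); output (N, O, 2H, 2W).
    """
    n, c, h, wdt = x.data.shape
    cw, o, kh, kw = w.data.shape
    if cw != c:
        raise ValueError("conv_transpose2d channel mismatch")
    out = np.zeros((n, o, 2 * h, 2 * wdt), dtype=x.data.dtype)
    x2 = x.data.reshape(n, c, h * wdt)
    for di in range(kh):
        for dj in range(kw):
            out[:, :, di::2, dj::2] = np.matmul(
                w.data[:, :, di, dj].T, x2
            ).reshape(n, o, h, wdt)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    def grad_fn(g):
        gw = np.zeros_like(w.data)
        gx = np.zeros_like(x.data)
        for di in range(kh):
            for dj in range(kw):
                gs = g[:, :, di::2, dj::2].reshape(n, o, h * wdt)
                gw[:, :, di, dj] = np.tensordot(x2, gs, axes=([0, 2], [0, 2]))
                gx += np.matmul(w.data[:, :, di, dj], gs).reshape(n, c, h, wdt)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, grad_fn)


# ---------------------------------------------------------------- pooling


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        return (gx,)

    return Tensor(out, (x,), grad_fn)


def channel_max(x: Tensor) -> Tensor:
    idx = x.data.argmax(axis=1, keepdims=True)
    out = np.take_along_axis(x.data, idx, axis=1)

    def grad_fn(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        return (gx,)

    return Tensor(out, (x,), grad_fn)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]
    out = x.data.mean(axis=1, keepdims=True)

    def grad_fn(g):
        return (np.broadcast_to(g / c, x.data.shape).astype(x.data.dtype),)

    return Tensor(out, (x,), grad_fn)


# -------------------------------------------------------------- upsample

_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix, half-pixel-center convention."""
    m = _BILINEAR_CACHE.get(n)
    if m is None:
        m = np.zeros((2 * n, n))
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            lo = min(max(i0, 0), n - 1)
            hi = min(max(i0 + 1, 0), n - 1)
            m[o, lo] += 1.0 - frac
            m[o, hi] += frac
        _BILINEAR_CACHE[n] = m
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    mh = _bilinear_matrix(h).astype(x.data.dtype)
    mw = _bilinear_matrix(w).astype(x.data.dtype)
    out = np.matmul(np.matmul(mh, x.data), mw.T)

    def grad_fn(g):
        return (np.matmul(np.matmul(mh.T, g), mw),)

    return Tensor(out, (x,), grad_fn)


# ------------------------------------------------------------------ loss


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    diff = pred.data - target
    n = diff.size

    def grad_fn(g):
        return ((2.0 / n) * g * diff,)

    return Tensor(np.asarray(np.mean(diff * diff)), (pred,), grad_fn)
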