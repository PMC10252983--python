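"""Brute-force loop-based reference implementations.

Deliberately naive (explicit Python loops, no vectorization, no shared code
with the package) so they can serve as independent oracles for the
filtering and network primitives.
"""

from __future__ import annotations

import numpy as np


def _reflect(i: int, n: int) -> int:
    """scipy.ndimage 'reflect' boundary: (d c b a | a b c d)."""
    if i < 0:
        i = -i - 1
    if i >= n:
        i = 2 * n - i - 1
    return i


def gaussian_kernel1d(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_loop(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur by explicit summation, reflective border."""
    k = gaussian_kernel1d(sigma)
    radius = len(k) // 2
    h, w = img.shape
    tmp = np.zeros_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for t in range(-radius, radius + 1):
                acc += k[t + radius] * img[_reflect(r + t, h), c]
            tmp[r, c] = acc
    out = np.zeros_like(tmp)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for t in range(-radius, radius + 1):
                acc += k[t + radius] * tmp[r, _reflect(c + t, w)]
            out[r, c] = acc
    return out


_K5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _blur5_axis_loop(x: np.ndarray, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    out = np.zeros_like(x, dtype=float)
    for i in range(n):
        for t in range(-2, 3):
            out[i] += _K5[t + 2] * x[_reflect(i + t, n)]
    return np.moveaxis(out, 0, axis)


def reduce_loop(x: np.ndarray) -> np.ndarray:
    """5-tap binomial blur then decimation by 2, explicit loops."""
    return _blur5_axis_loop(_blur5_axis_loop(x, 0), 1)[::2, ::2]


def _expand_axis_loop(x: np.ndarray, m: int, axis: int) -> np.ndarray:
    x = np.moveaxis(np.asarray(x, dtype=float), axis, 0)
    n = x.shape[0]
    out = np.zeros((m,) + x.shape[1:])
    for o in range(m):
        if o % 2 == 0:  # even phase: (1, 6, 1)/8 around sample o//2
            i = o // 2
            out[o] = (x[_reflect(i - 1, n)] + 6.0 * x[i] + x[_reflect(i + 1, n)]) / 8.0
        else:  # odd phase: neighbor average, edge-replicated
            i = o // 2
            out[o] = 0.5 * (x[i] + x[min(i + 1, n - 1)])
    return np.moveaxis(out, 0, axis)


def expand_loop(x: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    return _expand_axis_loop(_expand_axis_loop(x, target_shape[0], 0),
                             target_shape[1], 1)


def conv2d_loop(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 'same' cross-correlation with zero padding, explicit loops.

    x: (C, H, W); w: (O, C, k, k); returns (O, H, W).
    """
    c, h, wd = x.shape
    o, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((o, h, wd))
    for oc in range(o):
        for r in range(h):
            for cc in range(wd):
                acc = 0.0
                for ic in range(c):
                    for dr in range(kh):
                        for dc in range(kw):
                            rr, ccc = r + dr - ph, cc + dc - pw
                            if 0 <= rr < h and 0 <= ccc < wd:
                                acc += w[oc, ic, dr, dc] * x[ic, rr, ccc]
                if b is not None:
                    acc += b[oc]
                out[oc, r, cc] = acc
    return out


def spatial_attention_loop(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Channel max/mean pooling -> 7x7 conv -> sigmoid -> gate, per pixel.

    x: (C, H, W); w: (1, 2, 7, 7); b: (1,); returns gated x.
    """
    pooled = np.stack([x.max(axis=0), x.mean(axis=0)], axis=0)
    att = 1.0 / (1.0 + np.exp(-conv2d_loop(pooled, w, b)[0]))
    return x * att[None]


def additive_gate_loop(enc: np.ndarray, q: np.ndarray, w1: np.ndarray,
                       w2: np.ndarray, b: np.ndarray, psi_w: np.ndarray,
                       psi_b: float) -> np.ndarray:
    """sigmoid(psi . relu(W1 k + W2 q + b)) per pixel, explicit loops.

    enc: (Ce, H, W); q: (Cq, H, W); w1: (I, Ce); w2: (I, Cq); b: (I,);
    psi_w: (I,); returns the (H, W) gate map.
    """
    _, h, w = enc.shape
    gate = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            pre = w1 @ enc[:, r, c] + w2 @ q[:, r, c] + b
            pre = np.maximum(pre, 0.0)
            gate[r, c] = 1.0 / (1.0 + np.exp(-(psi_w @ pre + psi_b)))
    return gate
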