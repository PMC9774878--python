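"""Minimal feed-forward NN engine: layers with explicit backward passes.

Tensors are channels-last float32: images are (N, H, W, C), volumes are
(N, H, W, B, C).  Each layer caches what its backward pass needs during
forward; call forward then backward once per step.  Convolutions use
im2col + BLAS matmul with 'same' padding (output size = ceil(input/stride)),
which keeps encoder/decoder shapes exact mirrors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2D",
    "Conv3D",
    "ReLU",
    "Flatten",
    "Reshape",
    "ResizeNearest",
    "Sequential",
    "Adam",
]

DTYPE = np.float32


def _same_pad(n_in: int, k: int, s: int) -> tuple[int, int, int]:
    """Return (n_out, pad_before, pad_after) for 'same' padding."""
    n_out = -(-n_in // s)  # ceil
    total = max((n_out - 1) * s + k - n_in, 0)
    before = total // 2
    return n_out, before, total - before


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(DTYPE)
        b = np.zeros(n_out, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


class Conv2D(Layer):
    """3x3 (or kxk) 'same' convolution with stride, channels-last."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        super().__init__()
        fan_in = k * k * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k * k * c_in, c_out)).astype(DTYPE)
        b = np.zeros(c_out, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out

    def forward(self, x):
        n, h, w_in, c = x.shape
        k, s = self.k, self.stride
        if k == 1 and s == 1:  # pointwise: plain matmul, no im2col
            self._cache = ("1x1", x.shape, x.reshape(-1, c))
            y = self._cache[2] @ self.params[0] + self.params[1]
            return y.reshape(n, h, w_in, self.c_out)
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w_in, k, s)
        if pt or pb or pl or pr:
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (n, ho, wo, c, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, k * k * c
        )
        self._cache = (x.shape, xp.shape, (pt, pl), (ho, wo), cols)
        y = cols @ self.params[0] + self.params[1]
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, dy):
        if self._cache[0] == "1x1":
            _, xshape, xmat = self._cache
            dy_mat = dy.reshape(-1, self.c_out)
            self.grads[0][...] = xmat.T @ dy_mat
            self.grads[1][...] = dy_mat.sum(axis=0)
            return (dy_mat @ self.params[0].T).reshape(xshape)
        (xshape, xpshape, (pt, pl), (ho, wo), cols) = self._cache
        n, h, w_in, c = xshape
        k, s = self.k, self.stride
        dy_mat = dy.reshape(n * ho * wo, self.c_out)
        self.grads[0][...] = cols.T @ dy_mat
        self.grads[1][...] = dy_mat.sum(axis=0)
        dcols = (dy_mat @ self.params[0].T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros(xpshape, dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pt : pt + h, pl : pl + w_in, :]


class Conv3D(Layer):
    """k1 x k2 x k3 'same' convolution with per-axis stride, channels-last volumes."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: tuple[int, int, int],
        stride: tuple[int, int, int],
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = int(np.prod(k)) * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(DTYPE)
        b = np.zeros(c_out, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out

    def forward(self, x):
        n, h, w_in, d, c = x.shape
        (k1, k2, k3), (s1, s2, s3) = self.k, self.stride
        ho, p1a, p1b = _same_pad(h, k1, s1)
        wo, p2a, p2b = _same_pad(w_in, k2, s2)
        do, p3a, p3b = _same_pad(d, k3, s3)
        xp = np.pad(x, ((0, 0), (p1a, p1b), (p2a, p2b), (p3a, p3b), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k1, k2, k3), axis=(1, 2, 3))
        win = win[:, ::s1, ::s2, ::s3]  # (n, ho, wo, do, c, k1, k2, k3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
            n * ho * wo * do, k1 * k2 * k3 * c
        )
        self._cache = (x.shape, xp.shape, (p1a, p2a, p3a), (ho, wo, do), cols)
        y = cols @ self.params[0] + self.params[1]
        return y.reshape(n, ho, wo, do, self.c_out)

    def backward(self, dy):
        (xshape, xpshape, (p1a, p2a, p3a), (ho, wo, do), cols) = self._cache
        n, h, w_in, d, c = xshape
        (k1, k2, k3), (s1, s2, s3) = self.k, self.stride
        dy_mat = dy.reshape(-1, self.c_out)
        self.grads[0][...] = cols.T @ dy_mat
        self.grads[1][...] = dy_mat.sum(axis=0)
        dcols = (dy_mat @ self.params[0].T).reshape(n, ho, wo, do, k1, k2, k3, c)
        dxp = np.zeros(xpshape, dtype=DTYPE)
        for i in range(k1):
            for j in range(k2):
                for l in range(k3):
                    dxp[
                        :,
                        i : i + s1 * ho : s1,
                        j : j + s2 * wo : s2,
                        l : l + s3 * do : s3,
                        :,
                    ] += dcols[:, :, :, :, i, j, l, :]
        return dxp[:, p1a : p1a + h, p2a : p2a + w_in, p3a : p3a + d, :]


class ReLU(Layer):
    """Rectifier with a small negative slope (leaky) so units cannot die."""

    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = np.float32(slope)

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]):
        super().__init__()
        self.target = target

    def forward(self, x):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ResizeNearest(Layer):
    """Nearest-neighbour resize of the spatial (and band) axes to a target size.

    Works for (N, H, W, C) with a 2-tuple target or (N, H, W, B, C) with a
    3-tuple target.  Backward accumulates gradients over duplicated samples.
    """

    def __init__(self, target: tuple[int, ...]):
        super().__init__()
        self.target = target

    def forward(self, x):
        self._in_sizes = x.shape[1 : 1 + len(self.target)]
        self._idx = [
            (np.arange(t) * n_in) // t for t, n_in in zip(self.target, self._in_sizes)
        ]
        y = x
        for ax, idx in enumerate(self._idx, start=1):
            y = np.take(y, idx, axis=ax)
        return y

    def backward(self, dy):
        dx = dy
        for ax, (idx, n_in) in enumerate(zip(self._idx, self._in_sizes), start=1):
            shape = list(dx.shape)
            shape[ax] = n_in
            acc = np.zeros(shape, dtype=DTYPE)
            mov_acc = np.moveaxis(acc, ax, 0)
            mov_dy = np.moveaxis(dx, ax, 0)
            for o, i in enumerate(idx):
                mov_acc[i] += mov_dy[o]
            dx = acc
        return dx


class SpatialMoments(Layer):
    """Per-channel spatial mean and standard deviation: (N,H,W,C) -> (N,2C).

    Translation-invariant by construction; the std uses a small eps for a
    finite gradient at constant inputs.
    """

    def __init__(self, eps: float = 1e-6):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        n, h, w, c = x.shape
        mu = x.mean(axis=(1, 2))
        var = x.var(axis=(1, 2))
        sd = np.sqrt(var + self.eps)
        self._cache = (x, mu, sd, h * w)
        return np.concatenate([mu, sd], axis=1)

    def backward(self, dy):
        x, mu, sd, hw = self._cache
        c = mu.shape[1]
        dmu = dy[:, :c]
        dsd = dy[:, c:]
        dx = dmu[:, None, None, :] / hw + dsd[:, None, None, :] * (
            x - mu[:, None, None, :]
        ) / (hw * sd[:, None, None, :])
        return dx.astype(DTYPE)


class MultiHead(Layer):
    """Run several sub-stacks on one input and concatenate their outputs
    along the feature axis; backward sums the heads' input gradients."""

    def __init__(self, heads: list["Sequential"]):
        super().__init__()
        self.heads = heads

    def forward(self, x):
        outs = [head.forward(x) for head in self.heads]
        self._dims = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for head, d in zip(self.heads, self._dims):
            g = head.backward(dy[:, start : start + d])
            dx = g if dx is None else dx + g
            start += d
        return dx

    def param_pairs(self):
        for head in self.heads:
            yield from head.param_pairs()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_pairs(self):
        for layer in self.layers:
            if hasattr(layer, "param_pairs"):
                yield from layer.param_pairs()
            else:
                for p, g in zip(layer.params, layer.grads):
                    yield p, g


class Adam:
    """Adam optimiser over a fixed list of (param, grad) array pairs."""

    def __init__(self, pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(pairs)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
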