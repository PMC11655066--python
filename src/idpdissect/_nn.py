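"""Compact numpy neural-network core.

Implements exactly the layer set the two variational autoencoders in this
package need: dense layers, 2-D convolution / transposed convolution (im2col
based), tanh/sigmoid activations, and Adam.  Forward and backward passes are
written by hand and verified against finite differences in the test suite.

All arrays are float64; all randomness flows through an explicit
``numpy.random.Generator`` so that training is bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv2D",
    "ConvTranspose2D",
    "Tanh",
    "Sigmoid",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    """Fan-balanced uniform initialisation, limit sqrt(6/(fan_in+fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


# ---------------------------------------------------------------------------
# im2col helpers (kernel loops only over the k*k offsets, so cheap for 3x3)
# ---------------------------------------------------------------------------

def _out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def im2col(x, k: int, stride: int, pad: int):
    """x (N,C,H,W) -> columns (N, C*k*k, Ho*Wo)."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo))
    for i in range(k):
        i_end = i + stride * ho
        for j in range(k):
            j_end = j + stride * wo
            cols[:, :, i, j] = xp[:, :, i:i_end:stride, j:j_end:stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols, x_shape, k: int, stride: int, pad: int):
    """Adjoint of im2col: columns (N, C*k*k, Ho*Wo) -> accumulated (N,C,H,W)."""
    n, c, h, w = x_shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        i_end = i + stride * ho
        for j in range(k):
            j_end = j + stride * wo
            xp[:, :, i:i_end:stride, j:j_end:stride] += cols[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad:-pad, pad:-pad]


class Conv2D(Layer):
    """3x3-style convolution with 'same'-flavoured padding k//2."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = glorot_uniform(rng, fan_in, fan_out, (c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_shape(self, h: int, w: int):
        return (_out_size(h, self.k, self.stride, self.pad),
                _out_size(w, self.k, self.stride, self.pad))

    def forward(self, x):
        self._x_shape = x.shape
        n = x.shape[0]
        ho, wo = self.out_shape(x.shape[2], x.shape[3])
        self._cols = im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("fc,ncl->nfl", self.W, self._cols)
        return out.reshape(n, self.c_out, ho, wo) + self.b[None, :, None, None]

    def backward(self, g):
        n = g.shape[0]
        gf = g.reshape(n, self.c_out, -1)
        self.grads[0][...] = np.einsum("nfl,ncl->fc", gf, self._cols)
        self.grads[1][...] = gf.sum(axis=(0, 2))
        dcols = np.einsum("fc,nfl->ncl", self.W, gf)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2D(Layer):
    """Transposed convolution; ``out_hw`` pins the exact output size so a
    decoder can mirror the recorded shapes of its encoder."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 out_hw: tuple, rng: np.random.Generator):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.out_hw = out_hw
        expect = (_out_size(out_hw[0], k, stride, self.pad),
                  _out_size(out_hw[1], k, stride, self.pad))
        self._in_hw = expect
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = glorot_uniform(rng, fan_in, fan_out, (c_in, c_out * k * k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        n = x.shape[0]
        if x.shape[2:] != self._in_hw:
            raise ValueError(
                f"ConvTranspose2D expected input {self._in_hw}, got {x.shape[2:]}")
        self._xf = x.reshape(n, self.c_in, -1)
        cols = np.einsum("cf,ncl->nfl", self.W, self._xf)
        out = col2im(cols, (n, self.c_out) + tuple(self.out_hw),
                     self.k, self.stride, self.pad)
        return out + self.b[None, :, None, None]

    def backward(self, g):
        n = g.shape[0]
        gcols = im2col(g, self.k, self.stride, self.pad)
        self.grads[0][...] = np.einsum("ncl,nfl->cf", self._xf, gcols)
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        dx = np.einsum("cf,nfl->ncl", self.W, gcols)
        return dx.reshape(n, self.c_in, *self._in_hw)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def params_hash(layers) -> str:
    """Stable hash of all layer parameters (determinism checks)."""
    import hashlib

    h = hashlib.sha256()
    for layer in layers:
        for p in layer.params:
            h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()
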