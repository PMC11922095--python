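"""Compact numpy neural-network backend.

Implements exactly the layer zoo the split-latent autoencoder needs —
dense, strided convolution, transposed convolution, batch normalisation,
dropout, the usual activations — with hand-written backward passes and an
Adam optimiser.  All randomness (initialisation, dropout masks) is drawn
from an explicitly passed :class:`numpy.random.Generator`, so every forward
and backward pass is bit-reproducible given a seed.

Conventions
-----------
* Image tensors are NCHW; feature tensors are (n, features).
* ``forward(x, train=...)`` caches whatever ``backward`` needs; ``backward``
  receives the loss gradient w.r.t. the layer output and returns the
  gradient w.r.t. the input while accumulating parameter gradients.
* Convolutions use 4x4 kernels with stride 2 and padding 1, which halves
  (doubles, for the transposed version) each spatial dimension exactly.
"""

from __future__ import annotations

import numpy as np

#: Default parameter/compute dtype.  float32 halves memory traffic (the
#: bottleneck of CPU convolution) while leaving plenty of headroom for the
#: loss scales involved; tests that need tighter numerics rebind this.
DTYPE = np.float32

__all__ = [
    "Layer", "Dense", "Conv2d", "ConvTranspose2d", "BatchNorm", "Dropout",
    "LeakyReLU", "ReLU", "Tanh", "Flatten", "Reshape", "Sequential", "Adam",
    "softmax", "sigmoid", "clip_gradients",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# im2col helpers shared by Conv2d and ConvTranspose2d
# ---------------------------------------------------------------------------

def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, c, ho, wo, k, k), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    )
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)


def col2im(col: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    col6 = col.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * pad + stride, w + 2 * pad + stride), dtype=col.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += col6[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameter-free, shape-preserving by default."""

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T


class Conv2d(Layer):
    """Strided convolution; kernel 4, stride 2, pad 1 halves H and W."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=True):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        ho = _out_size(h, self.k, self.stride, self.pad)
        wo = _out_size(w, self.k, self.stride, self.pad)
        self._col = im2col(x, self.k, self.stride, self.pad)
        out = self._col @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, co, ho, wo = grad.shape
        g2 = grad.transpose(0, 2, 3, 1).reshape(-1, co)
        self.gW += (g2.T @ self._col).reshape(self.W.shape)
        self.gb += g2.sum(axis=0)
        gcol = g2 @ self.W.reshape(co, -1)
        return col2im(gcol, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed convolution; kernel 4, stride 2, pad 1 doubles H and W.

    Forward is the adjoint (col2im) of the matching strided convolution,
    backward its im2col — the exact mirror used by the decoder.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, k, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=True):
        n, ci, h, w = x.shape
        self._x = x
        co = self.W.shape[1]
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        x2 = x.transpose(0, 2, 3, 1).reshape(-1, ci)
        col = x2 @ self.W.reshape(ci, -1)  # (N*h*w, co*k*k)
        out = col2im(col, (n, co, ho, wo), self.k, self.stride, self.pad)
        return out + self.b[None, :, None, None]

    def backward(self, grad):
        n, ci, h, w = self._x.shape
        co = self.W.shape[1]
        gcol = im2col(grad, self.k, self.stride, self.pad)  # (N*h*w, co*k*k)
        x2 = self._x.transpose(0, 2, 3, 1).reshape(-1, ci)
        self.gW += (x2.T @ gcol).reshape(self.W.shape)
        self.gb += grad.sum(axis=(0, 2, 3))
        gx = gcol @ self.W.reshape(ci, -1).T
        return gx.reshape(n, h, w, ci).transpose(0, 3, 1, 2)


class BatchNorm(Layer):
    """Batch normalisation over axis 0 (2D input) or axes (0,2,3) (NCHW)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels, dtype=DTYPE)
        self.beta = np.zeros(n_channels, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v, ndim):
        return v if ndim == 2 else v[:, None, None]

    def forward(self, x, train=True):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(istd, x.ndim)
        self._xhat, self._istd, self._train = xhat, istd, train
        return self._expand(self.gamma, x.ndim) * xhat + self._expand(self.beta, x.ndim)

    def backward(self, grad):
        axes = self._axes(grad)
        xhat, istd = self._xhat, self._istd
        self.ggamma += (grad * xhat).sum(axis=axes)
        self.gbeta += grad.sum(axis=axes)
        g = grad * self._expand(self.gamma, grad.ndim)
        if not self._train:
            return g * self._expand(istd, grad.ndim)
        m = grad.size / grad.shape[1] if grad.ndim == 4 else grad.shape[0]
        gsum = g.sum(axis=axes)
        gxhat_sum = (g * xhat).sum(axis=axes)
        gx = (g - self._expand(gsum / m, grad.ndim)
              - xhat * self._expand(gxhat_sum / m, grad.ndim))
        return gx * self._expand(istd, grad.ndim)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs a Generator attached."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=True):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout layer has no RNG attached")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def attach_rng(self, rng: np.random.Generator) -> "Sequential":
        for l in self.layers:
            if isinstance(l, Dropout):
                l.rng = rng
        return self

    @property
    def dtype(self):
        for p in self.params():
            return p.dtype
        return np.dtype(DTYPE)

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=self.dtype)
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        grad = np.asarray(grad, dtype=self.dtype)
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def weight_layers(self) -> list[Layer]:
        """Layers carrying a weight matrix/kernel (Dense/Conv variants)."""
        return [l for l in self.layers if isinstance(l, (Dense, Conv2d, ConvTranspose2d))]


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

def clip_gradients(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place to a global L2 norm cap; returns the norm."""
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
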