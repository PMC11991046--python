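"""Minimal NumPy layer library with manual backpropagation.

Shapes follow the (batch, channels, length) convention for 1-D signal
layers.  Each layer instance caches whatever its backward pass needs
during ``forward``; a layer is therefore used at most once per forward
pass of a network.  All parameters live in :class:`Param` objects so
optimizers can iterate over them generically.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

#: dtype used for parameters and activations; float32 keeps the CPU cost of
#: the convolutional models manageable.  Tests that need tighter gradients
#: upcast parameter values to float64 explicitly.
DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: ``forward``/``backward`` plus parameter discovery."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train=True):
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """1-D convolution (cross-correlation), stride 1.

    ``padding`` is the number of zeros added on each side: 0 gives a
    "valid" convolution, ``(k - 1) // 2`` preserves length for odd ``k``,
    and ``k - 1`` gives the "full" convolution used by the transposed
    variant.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int = 0,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel, self.padding = in_ch, out_ch, kernel, padding
        if zero_init:
            w = np.zeros((out_ch, in_ch * kernel))
        else:
            w = _he_init(rng, (out_ch, in_ch * kernel), in_ch * kernel)
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch))
        self._cols = None
        self._in_shape = None

    def forward(self, x, train=True):
        n, c, length = x.shape
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        l_out = length + 2 * self.padding - self.kernel + 1
        self._x_pad = x
        self._in_shape = (n, c, length)
        # shifted-matmul form: y[n,l,o] = sum_k x[n,:,l+k] . w[o,:,k]
        w3 = self.w.value.reshape(self.out_ch, self.in_ch, self.kernel)
        y = np.empty((n, l_out, self.out_ch), dtype=x.dtype)
        y[...] = self.b.value
        for k in range(self.kernel):
            y += x[:, :, k:k + l_out].transpose(0, 2, 1) @ w3[:, :, k].T
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        n, _, l_out = grad.shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 1))  # (n, L_out, out_ch)
        g2 = g.reshape(n * l_out, self.out_ch)
        self.b.grad += g2.sum(axis=0)
        w3 = self.w.value.reshape(self.out_ch, self.in_ch, self.kernel)
        gw3 = self.w.grad.reshape(self.out_ch, self.in_ch, self.kernel)
        x = self._x_pad
        _, c, length = self._in_shape
        gx = np.zeros((n, c, length + 2 * self.padding), dtype=grad.dtype)
        for k in range(self.kernel):
            xk = x[:, :, k:k + l_out]
            gw3[:, :, k] += g2.T @ xk.transpose(0, 2, 1).reshape(n * l_out, c)
            gx[:, :, k:k + l_out] += (g @ w3[:, :, k]).transpose(0, 2, 1)
        if self.padding:
            gx = gx[:, :, self.padding:-self.padding]
        return gx


class ConvTranspose1d(Module):
    """Transposed 1-D convolution, stride 1, no padding: L_out = L_in + k - 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator | None = None):
        self.conv = Conv1d(in_ch, out_ch, kernel, padding=kernel - 1, rng=rng)

    def forward(self, x, train=True):
        return self.conv.forward(x, train=train)

    def backward(self, grad):
        return self.conv.backward(grad)


class MaxPool1d(Module):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel
        self._argmax = None
        self._in_shape = None

    def forward(self, x, train=True):
        n, c, length = x.shape
        k = self.kernel
        l_out = length // k
        xv = x[:, :, :l_out * k].reshape(n, c, l_out, k)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = x.shape
        return xv.max(axis=3)

    def backward(self, grad):
        n, c, length = self._in_shape
        k = self.kernel
        l_out = length // k
        gx = np.zeros((n, c, l_out, k), dtype=grad.dtype)
        np.put_along_axis(gx, self._argmax[..., None], grad[..., None], axis=3)
        gx = gx.reshape(n, c, l_out * k)
        if l_out * k < length:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, length - l_out * k)))
        return gx


class Upsample1d(Module):
    """Linear-interpolation resampling to a target length.

    Implemented as multiplication by a fixed (L_out x L_in) interpolation
    matrix so the backward pass is its exact transpose.
    """

    _matrices: dict[tuple[int, int], np.ndarray] = {}

    def __init__(self, size: int | None = None, scale: int | None = None):
        if (size is None) == (scale is None):
            raise ValueError("give exactly one of size or scale")
        self.size, self.scale = size, scale
        self._mat = None

    @classmethod
    def _matrix(cls, l_in: int, l_out: int) -> np.ndarray:
        key = (l_in, l_out)
        if key not in cls._matrices:
            a = np.zeros((l_out, l_in))
            for i in range(l_out):
                src = (i + 0.5) * l_in / l_out - 0.5
                src = min(max(src, 0.0), l_in - 1.0)
                lo = int(math.floor(src))
                hi = min(lo + 1, l_in - 1)
                frac = src - lo
                a[i, lo] += 1.0 - frac
                a[i, hi] += frac
            cls._matrices[key] = a.astype(DTYPE)
        return cls._matrices[key]

    def forward(self, x, train=True):
        l_in = x.shape[2]
        l_out = self.size if self.size is not None else l_in * self.scale
        self._mat = self._matrix(l_in, l_out)
        return x @ self._mat.T

    def backward(self, grad):
        return grad @ self._mat


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng if rng is not None else np.random.default_rng(0)
        w = np.zeros((out_dim, in_dim)) if zero_init else _he_init(rng, (out_dim, in_dim), in_dim)
        self.w = Param(w)
        self.b = Param(np.zeros(out_dim))
        self._x = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.w.grad += g2.T @ x2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.w.value


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GELU(Module):
    """Exact Gaussian error linear unit, x * Phi(x)."""

    def forward(self, x, train=True):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        return x * self._cdf

    def backward(self, grad):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return grad * (self._cdf + x * pdf)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._train = train
        return self.gamma.value[None, :, None] * self._xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        if not self._train:
            return g / std[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        return (g - g.mean(axis=(0, 2), keepdims=True)
                - xhat * (g * xhat).mean(axis=(0, 2), keepdims=True)) / std[None, :, None]


class GroupNorm(Module):
    """Group normalization over (channel-group, length) per sample."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups, self.channels, self.eps = groups, channels, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def forward(self, x, train=True):
        n, c, length = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * length)
        mean = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = ((xg - mean) / self._std).reshape(n, c, length)
        return self.gamma.value[None, :, None] * self._xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        n, c, length = grad.shape
        g = self.groups
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gh = (grad * self.gamma.value[None, :, None]).reshape(n, g, (c // g) * length)
        xh = xhat.reshape(n, g, (c // g) * length)
        gx = (gh - gh.mean(axis=2, keepdims=True)
              - xh * (gh * xh).mean(axis=2, keepdims=True)) / self._std
        return gx.reshape(n, c, length)


class SelfAttention1d(Module):
    """Single-head scaled dot-product self-attention over the time axis.

    Residual: output = x + W_o(softmax(QK^T / sqrt(C)) V).
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.wq = Linear(channels, channels, rng=rng)
        self.wk = Linear(channels, channels, rng=rng)
        self.wv = Linear(channels, channels, rng=rng)
        self.wo = Linear(channels, channels, rng=rng, zero_init=True)

    def forward(self, x, train=True):
        xt = x.transpose(0, 2, 1)                         # (n, L, C)
        q = self.wq.forward(xt)
        k = self.wk.forward(xt)
        v = self.wv.forward(xt)
        scores = q @ k.transpose(0, 2, 1) / math.sqrt(self.channels)
        scores -= scores.max(axis=2, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=2, keepdims=True)           # (n, L, L)
        ctx = attn @ v
        out = self.wo.forward(ctx)
        self._cache = (q, k, v, attn, ctx)
        return x + out.transpose(0, 2, 1)

    def backward(self, grad):
        q, k, v, attn, ctx = self._cache
        g_out = grad.transpose(0, 2, 1)                   # (n, L, C)
        g_ctx = self.wo.backward(g_out)
        g_attn = g_ctx @ v.transpose(0, 2, 1)
        g_v = attn.transpose(0, 2, 1) @ g_ctx
        # softmax backward, rows of attn
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=2, keepdims=True))
        g_scores /= math.sqrt(self.channels)
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 2, 1) @ q
        g_xt = self.wq.backward(g_q) + self.wk.backward(g_k) + self.wv.backward(g_v)
        return grad + g_xt.transpose(0, 2, 1)


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


def mse(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements and its gradient."""
    diff = pred - target
    return float((diff * diff).mean()), 2.0 * diff / diff.size
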