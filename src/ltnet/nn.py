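"""Minimal deterministic CNN stack on numpy.

Implements exactly the operators the LTNet architecture needs — grouped /
depthwise 2-D convolution, batch normalization, hard-swish, squeeze-and-
excitation gating, dense layers, global average pooling — with hand-written
backward passes, plus Adam and softmax cross-entropy. Everything is seeded
explicitly; two builds from the same seed produce bit-identical weights.

Layers follow a tiny protocol: ``forward(x, train)``, ``backward(dy)``
(valid after a forward), and ``params()`` returning :class:`Param` objects.
Default dtype is float32; pass ``dtype=np.float64`` for gradient checking.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return int(self.data.size)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2d(Layer):
    """2-D convolution with 'same'-style padding and group support.

    ``groups == in_channels`` gives a depthwise convolution. Convolutions
    that feed a BatchNorm are conventionally built with ``bias=False``; a
    bias re-appears when the BN is folded in at inference time.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 name: str = "conv", dtype=None):
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        dtype = dtype or DEFAULT_DTYPE
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel * kernel
        self.weight = Param(
            f"{name}.weight",
            _uniform_init(rng, (out_channels, in_channels // groups, kernel, kernel), fan_in, dtype),
        )
        self.bias = Param(f"{name}.bias", np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, x: np.ndarray):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (x.shape[2] - k) // s + 1
        wo = (x.shape[3] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
        return np.ascontiguousarray(cols), x.shape, (ho, wo)

    def forward(self, x, train=False):
        n = x.shape[0]
        g = self.groups
        cols, padded_shape, (ho, wo) = self._im2col(x)
        cg = self.in_channels // g
        og = self.out_channels // g
        k = self.kernel
        cols_g = cols.reshape(n, g, cg * k * k, ho * wo)
        w = self.weight.data.reshape(g, og, cg * k * k)
        out = np.einsum("ngil,goi->ngol", cols_g, w, optimize=True)
        out = out.reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (cols_g, padded_shape, x.shape, (ho, wo))
        return out

    def backward(self, dy):
        cols_g, padded_shape, x_shape, (ho, wo) = self._cache
        n = dy.shape[0]
        g, k, s, p = self.groups, self.kernel, self.stride, self.padding
        cg = self.in_channels // g
        og = self.out_channels // g
        dy_g = dy.reshape(n, g, og, ho * wo)
        w = self.weight.data.reshape(g, og, cg * k * k)
        dw = np.einsum("ngol,ngil->goi", dy_g, cols_g, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcols = np.einsum("ngol,goi->ngil", dy_g, w, optimize=True)
        dcols = dcols.reshape(n, self.in_channels, k, k, ho, wo)
        dxp = np.zeros((n, self.in_channels, padded_shape[2], padded_shape[3]), dtype=dy.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, :, ki, kj]
        if p:
            dxp = dxp[:, :, p:-p or None, p:-p or None]
        return dxp[:, :, : x_shape[2], : x_shape[3]]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training uses batch statistics and updates running mean/variance with
    exponential momentum; evaluation uses the running statistics. Gamma and
    beta are the trainable tensors; the running statistics are buffers.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn", dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dy * g * inv_std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        dx = (dxhat
              - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv_std[None, :, None, None]


class Hswish(Layer):
    """Hard swish: x * clip(x + 3, 0, 6) / 6."""

    def forward(self, x, train=False):
        self._x = x
        return hswish(x)

    def backward(self, dy):
        x = self._x
        grad = np.where(x <= -3, 0.0, np.where(x >= 3, 1.0, (2 * x + 3) / 6.0))
        return dy * grad.astype(dy.dtype)


def hswish(x):
    """Hard-swish activation, elementwise: ``x * min(max(x + 3, 0), 6) / 6``."""
    x = np.asarray(x)
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy):
        return dy * self._mask


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "linear", dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        rng = rng or np.random.default_rng(0)
        self.weight = Param(f"{name}.weight",
                            _uniform_init(rng, (out_features, in_features), in_features, dtype))
        self.bias = Param(f"{name}.bias", np.zeros(out_features, dtype=dtype)) if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class SqueezeExcite(Layer):
    """Channel attention: GAP -> dense C->C/r -> ReLU -> dense C/r->C -> sigmoid gate."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator | None = None,
                 name: str = "se", dtype=None):
        if channels % ratio:
            raise ValueError(f"se_ratio {ratio} must divide channels {channels}")
        hidden = channels // ratio
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(channels, hidden, rng=rng, name=f"{name}.fc1", dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, name=f"{name}.fc2", dtype=dtype)
        self.relu = ReLU()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        z = x.mean(axis=(2, 3))
        a = self.relu.forward(self.fc1.forward(z, train), train)
        s = _sigmoid(self.fc2.forward(a, train))
        self._cache = (x, s, h * w)
        return x * s[:, :, None, None]

    def backward(self, dy):
        x, s, hw = self._cache
        ds = (dy * x).sum(axis=(2, 3))
        dx = dy * s[:, :, None, None]
        dpre = ds * s * (1.0 - s)
        da = self.fc2.backward(dpre)
        dz = self.fc1.backward(self.relu.backward(da))
        dx += dz[:, :, None, None] / hw
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits.

    Returns ``(loss, dlogits)``; labels are integer class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-30)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam with the standard bias correction; state keyed by parameter identity."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.data -= (self.lr * (m / b1t)
                       / (np.sqrt(v / b2t) + self.eps)).astype(p.data.dtype)
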