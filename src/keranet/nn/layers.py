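"""Trainable layers with explicit forward/backward passes (NumPy).

Data layout is channels-last: activations have shape (N, H, W, C) for
spatial layers and (N, C) after global average pooling. Convolutions use
"same" padding (symmetric, pad = 1 for 3×3 kernels) and carry no bias —
each is followed by batch normalization. The implementations favor clarity
and vectorization over peak speed; the loop over the 3×3 kernel taps keeps
memory flat while staying fully vectorized over the batch.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _out_size(n: int, stride: int) -> int:
    # "same" padding with 3x3 kernel and symmetric pad 1
    return (n - 1) // stride + 1


def _tap(xp: np.ndarray, i: int, j: int, stride: int, ho: int, wo: int) -> np.ndarray:
    return xp[:, i : i + stride * (ho - 1) + 1 : stride,
              j : j + stride * (wo - 1) + 1 : stride, :]


class Conv2D(Layer):
    """Standard 3×3 convolution, stride s, same padding, no bias."""

    def __init__(self, in_channels: int, filters: int, stride: int,
                 rng: np.random.Generator, kernel: int = 3, name: str = "conv"):
        self.stride = stride
        self.kernel = kernel
        fan_in = kernel * kernel * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, in_channels, filters))
        self.w = Param(w, name=f"{name}/kernel")
        self._xp = None

    def params(self):
        return [self.w]

    def forward(self, x, training=False):
        k, s = self.kernel, self.stride
        n, h, w, _ = x.shape
        ho, wo = _out_size(h, s), _out_size(w, s)
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp = xp
        self._out_hw = (ho, wo)
        out = np.zeros((n, ho, wo, self.w.value.shape[3]), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                out += _tap(xp, i, j, s, ho, wo) @ self.w.value[i, j]
        return out

    def backward(self, grad):
        k, s = self.kernel, self.stride
        xp = self._xp
        ho, wo = self._out_hw
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = _tap(xp, i, j, s, ho, wo)
                self.w.grad[i, j] += np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + s * (ho - 1) + 1 : s,
                    j : j + s * (wo - 1) + 1 : s, :] += grad @ self.w.value[i, j].T
        pad = k // 2
        return dxp[:, pad:xp.shape[1] - pad, pad:xp.shape[2] - pad, :]


class DepthwiseConv2D(Layer):
    """Depthwise 3×3 convolution: one spatial filter per channel."""

    def __init__(self, channels: int, stride: int, rng: np.random.Generator,
                 name: str = "dwconv"):
        self.stride = stride
        w = rng.normal(0.0, np.sqrt(2.0 / 9.0), size=(3, 3, channels))
        self.w = Param(w, name=f"{name}/depthwise_kernel")
        self._xp = None

    def params(self):
        return [self.w]

    def forward(self, x, training=False):
        s = self.stride
        n, h, w, c = x.shape
        ho, wo = _out_size(h, s), _out_size(w, s)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        self._out_hw = (ho, wo)
        out = np.zeros((n, ho, wo, c), dtype=DTYPE)
        for i in range(3):
            for j in range(3):
                out += _tap(xp, i, j, s, ho, wo) * self.w.value[i, j]
        return out

    def backward(self, grad):
        s = self.stride
        xp = self._xp
        ho, wo = self._out_hw
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                patch = _tap(xp, i, j, s, ho, wo)
                self.w.grad[i, j] += np.einsum("nhwc,nhwc->c", patch, grad)
                dxp[:, i : i + s * (ho - 1) + 1 : s,
                    j : j + s * (wo - 1) + 1 : s, :] += grad * self.w.value[i, j]
        return dxp[:, 1:-1, 1:-1, :]


class PointwiseConv2D(Layer):
    """1×1 convolution mixing channels, no bias."""

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator,
                 name: str = "pwconv"):
        w = rng.normal(0.0, np.sqrt(2.0 / in_channels), size=(in_channels, filters))
        self.w = Param(w, name=f"{name}/kernel")
        self._x = None

    def params(self):
        return [self.w]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value

    def backward(self, grad):
        self.w.grad += np.tensordot(self._x, grad, axes=([0, 1, 2], [0, 1, 2]))
        return grad @ self.w.value.T


class BatchNorm(Layer):
    """Per-channel batch normalization (trainable scale and shift).

    Uses batch statistics in training and exponential running averages at
    inference. The momentum default of 0.9 keeps the running estimates
    close to the current weights even when an epoch contains only a
    handful of optimizer steps.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels), name=f"{name}/gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}/beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, axes, x.size // x.shape[-1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv_std, axes, m = self._cache
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        return (self.gamma.value * inv_std / m) * (m * grad - dbeta - xhat * dgamma)

    def forward_calibrate(self, x: np.ndarray) -> np.ndarray:
        """Set the running statistics to this batch's population statistics.

        Used for precise-BN inference: after weights move, one pass over
        (a large batch of) the training data re-estimates the population
        mean/variance so inference-mode normalization matches what the
        current weights were trained against.
        """
        axes = tuple(range(x.ndim - 1))
        self.running_mean = x.mean(axis=axes)
        self.running_var = x.var(axis=axes)
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Layer):
    """Average each feature map to one value: (N, H, W, C) → (N, C)."""

    def forward(self, x, training=False):
        self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               (grad.shape[0], h, w, grad.shape[1])).copy()


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    """Fully connected layer with bias."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 name: str = "dense"):
        limit = np.sqrt(6.0 / (in_features + units))
        self.w = Param(rng.uniform(-limit, limit, size=(in_features, units)),
                       name=f"{name}/kernel")
        self.b = Param(np.zeros(units), name=f"{name}/bias")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Softmax(Layer):
    """Softmax over the last axis."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=-1, keepdims=True))
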