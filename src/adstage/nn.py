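"""Minimal NumPy neural-network layers with explicit backpropagation.

All tensors are float32 in NHWC layout (batch, height, width, channels).
Each layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``; input
gradients are first-class because saliency maps need them.

Convolutions are stride-1 with "same" zero padding, evaluated as a
shift-and-accumulate sum of k*k channel-mixing matmuls — on CPU this beats
an explicit im2col because no patch matrix is ever materialized.
Down/up-sampling is by 2x2 max-pooling and 2x2-stride-2 transposed
convolution, the classic U-Net arrangement.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Linear",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "he_normal",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 convolution with odd kernel and "same" zero padding.

    Weight shape is (k, k, C_in, C_out); the forward pass is
    ``y = sum_ij shift_ij(x) @ W[i, j] + b``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(he_normal(
            rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        y = np.empty((n, h, w, self.out_channels), dtype=np.float32)
        y[...] = self.bias.data
        wk = self.weight.data
        for i in range(k):
            for j in range(k):
                y += xp[:, i:i + h, j:j + w, :] @ wk[i, j]
        self._xp = xp
        self._hw = (h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        k, p = self.k, self.pad
        xp, wk = self._xp, self.weight.data
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(-1, dy.shape[-1])
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :])
                self.weight.grad[i, j] += xs.reshape(-1, xs.shape[-1]).T @ dyf
                dxp[:, i:i + h, j:j + w, :] += dy @ wk[i, j].T
        self.bias.grad += dy.sum(axis=(0, 1, 2))
        return np.ascontiguousarray(dxp[:, p:p + h, p:p + w, :]) if p else dxp

    @property
    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (doubles spatial size)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        # each output pixel sees exactly one input pixel
        self.weight = Param(he_normal(rng, (in_channels, out_channels * 4),
                                      in_channels))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.out_channels
        y = x @ self.weight.data                      # (N, H, W, F*4)
        y = y.reshape(n, h, w, 2, 2, f).transpose(0, 1, 3, 2, 4, 5)
        y = np.ascontiguousarray(y).reshape(n, 2 * h, 2 * w, f)
        y += self.bias.data
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x.shape
        f = self.out_channels
        # undo the forward pixel-shuffle: (N,2H,2W,F) -> (N*H*W, 4F) with
        # columns in the same (di, dj, f) order as the weight matrix
        d = dy.reshape(n, h, 2, w, 2, f).transpose(0, 1, 3, 2, 4, 5)
        d = np.ascontiguousarray(d).reshape(n * h * w, 4 * f)
        xf = np.ascontiguousarray(self._x).reshape(n * h * w, c)
        self.weight.grad += xf.T @ d
        self.bias.grad += dy.sum(axis=(0, 1, 2))
        dx = d @ self.weight.data.T
        return dx.reshape(n, h, w, c)

    @property
    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; ties resolve to the first element
    in (top-left, top-right, bottom-left, bottom-right) order."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class GlobalAvgPool2d(Layer):
    """Adaptive average pooling to 1x1, returned as (N, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w),
                               self._shape).astype(dy.dtype).copy()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Param(he_normal(rng, (in_features, out_features), in_features))
        self.bias = Param(np.zeros(out_features, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy).astype(dy.dtype)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # clip |x| at 60: sigmoid saturates there and float32 exp stays finite
        self._y = np.clip(x, -60.0, 60.0)
        np.negative(self._y, out=self._y)
        np.exp(self._y, out=self._y)
        self._y += 1.0
        np.reciprocal(self._y, out=self._y)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``training`` is False."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * np.square(p.grad)
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    grad = ((p - onehot) / n).astype(np.float32)
    return loss, grad
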