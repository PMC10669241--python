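"""Minimal dense/convolutional layer core with analytic backprop and Adam.

Kept deliberately small: 1-D convolutions with 'same' padding, max pooling,
stride-2 transposed convolutions for upsampling, dense layers, ReLU, and a
sequential container.  Shapes follow the (batch, length, channels)
convention.  Gradients are exact (verified against central finite
differences in the test suite), and all initialization is driven by an
explicit ``numpy.random.Generator`` so training is reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _he(rng: np.random.Generator, shape, fan_in) -> np.ndarray:
    # scaled for ReLU stacks; keeps activation variance stable with depth
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv1D(Layer):
    """1-D convolution with 'same' padding and unit stride.

    Input (N, L, C_in) -> output (N, L, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.W = Param(_glorot(rng, (kernel * c_in, c_out), kernel * c_in, c_out))
        self.b = Param(np.zeros(c_out))
        self._pad_left = (kernel - 1) // 2
        self._pad_right = kernel - 1 - self._pad_left

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        xp = np.pad(x, ((0, 0), (self._pad_left, self._pad_right), (0, 0)))
        # (N, L, C, K) -> (N, L, K*C)
        win = sliding_window_view(xp, self.kernel, axis=1)
        n, length = x.shape[0], x.shape[1]
        return win.transpose(0, 1, 3, 2).reshape(n, length, self.kernel * self.c_in)

    def forward(self, x):
        self._shape = x.shape
        self._col = self._im2col(x)
        return self._col @ self.W.value + self.b.value

    def backward(self, grad):
        n, length, _ = self._shape
        kc = self.kernel * self.c_in
        self.W.grad += self._col.reshape(-1, kc).T @ grad.reshape(-1, self.c_out)
        self.b.grad += grad.sum(axis=(0, 1))
        dcol = (grad @ self.W.value.T).reshape(n, length, self.kernel, self.c_in)
        dxp = np.zeros((n, length + self.kernel - 1, self.c_in))
        for k in range(self.kernel):
            dxp[:, k : k + length, :] += dcol[:, :, k, :]
        return dxp[:, self._pad_left : self._pad_left + length, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x):
        n, length, c = x.shape
        if length % self.pool:
            raise ValueError(f"length {length} not divisible by pool {self.pool}")
        self._shape = x.shape
        blocks = x.reshape(n, length // self.pool, self.pool, c)
        self._arg = blocks.argmax(axis=2)
        return np.take_along_axis(blocks, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        n, length, c = self._shape
        dblocks = np.zeros((n, length // self.pool, self.pool, c))
        np.put_along_axis(dblocks, self._arg[:, :, None, :], grad[:, :, None, :], axis=2)
        return dblocks.reshape(n, length, c)


class ConvTranspose1D(Layer):
    """Stride-2, kernel-2 transposed convolution: exact 2x upsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_glorot(rng, (2, c_in, c_out), c_in, 2 * c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        n, length, _ = x.shape
        out = np.empty((n, 2 * length, self.c_out))
        out[:, 0::2, :] = x @ self.W.value[0] + self.b.value
        out[:, 1::2, :] = x @ self.W.value[1] + self.b.value
        return out

    def backward(self, grad):
        x = self._x
        g0, g1 = grad[:, 0::2, :], grad[:, 1::2, :]
        flat = x.reshape(-1, self.c_in)
        self.W.grad[0] += flat.T @ g0.reshape(-1, self.c_out)
        self.W.grad[1] += flat.T @ g1.reshape(-1, self.c_out)
        self.b.grad += grad.sum(axis=(0, 1))
        return g0 @ self.W.value[0].T + g1 @ self.W.value[1].T


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """Reshape per-sample to a fixed (length, channels) target."""

    def __init__(self, target: tuple[int, int]):
        self.target = target

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], *self.target)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_weights(model: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def set_weights(model: Layer, weights: list[np.ndarray]) -> None:
    for p, w in zip(model.params(), weights):
        p.value[...] = w
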