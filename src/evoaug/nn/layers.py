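"""Layers with explicit forward/backward passes.

Every layer exposes ``forward(x, train)`` and ``backward(grad)`` (returning
the gradient with respect to its input), plus ``params`` / ``grads`` lists
for the optimizer and ``get_state`` / ``set_state`` for checkpointing.
Shapes are channels-last: convolutional feature maps are ``(B, L, C)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def output_length(self, length: int) -> int:
        """Spatial length after this layer (identity for non-spatial ops)."""
        return length

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution, stride 1, channels-last.

    Weight shape ``(width, in_channels, filters)``; He-uniform init.
    """

    def __init__(self, in_channels: int, filters: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.width = width
        fan_in = width * in_channels
        bound = np.sqrt(6.0 / fan_in)
        self.w = rng.uniform(-bound, bound, size=(width, in_channels, filters)).astype(np.float64)
        self.b = np.zeros(filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._windows: np.ndarray | None = None

    def output_length(self, length: int) -> int:
        out = length - self.width + 1
        if out < 1:
            raise ValueError(f"Conv1D(width={self.width}) input length {length} too short")
        return out

    def linear_response(self, x: np.ndarray) -> np.ndarray:
        """Raw convolution output without caching (used by interpretability)."""
        windows = sliding_window_view(x, self.width, axis=1)  # (B, Lout, C, W)
        return np.einsum("blcw,wcf->blf", windows, self.w, optimize=True) + self.b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._windows = sliding_window_view(x, self.width, axis=1)
        self._in_length = x.shape[1]
        return np.einsum("blcw,wcf->blf", self._windows, self.w, optimize=True) + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("blcw,blf->wcf", self._windows, grad, optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        # full correlation of grad with the position-flipped kernel
        gpad = np.pad(grad, ((0, 0), (self.width - 1, self.width - 1), (0, 0)))
        gwin = sliding_window_view(gpad, self.width, axis=1)  # (B, L, F, W)
        return np.einsum("blfw,wcf->blc", gwin, self.w[::-1], optimize=True)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / in_features)
        self.w = rng.uniform(-bound, bound, size=(in_features, units)).astype(np.float64)
        self.b = np.zeros(units)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class BatchNorm(Layer):
    """Batch normalisation over batch (and positions, for 3-D inputs).

    Keeps exponential running statistics for evaluation mode, where the
    layer is an affine map and therefore cleanly differentiable for
    attribution.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return (0, 1) if x.ndim == 3 else (0,)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        self._train = train
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = self._axes(grad)
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        if not self._train:
            return grad * self.gamma * self._invstd
        n = self._n
        gxhat = grad * self.gamma
        return (
            self._invstd
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=axes)
                - self._xhat * (gxhat * self._xhat).sum(axis=axes)
            )
        )

    def get_state(self) -> list[np.ndarray]:
        return [self.gamma.copy(), self.beta.copy(), self.running_mean.copy(), self.running_var.copy()]

    def set_state(self, state: list[np.ndarray]) -> None:
        self.gamma[...], self.beta[...] = state[0], state[1]
        self.running_mean = state[2].copy()
        self.running_var = state[3].copy()


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = pool size); trailing remainder dropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def output_length(self, length: int) -> int:
        out = length // self.size
        if out < 1:
            raise ValueError(f"MaxPool1D(size={self.size}) input length {length} too short")
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, length, c = x.shape
        lout = length // self.size
        self._in_shape = x.shape
        xr = x[:, : lout * self.size].reshape(b, lout, self.size, c)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, length, c = self._in_shape
        lout = grad.shape[1]
        out = np.zeros((b, lout, self.size, c))
        np.put_along_axis(out, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        full = np.zeros(self._in_shape)
        full[:, : lout * self.size] = out.reshape(b, lout * self.size, c)
        return full


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)
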