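"""Sequential container with checkpointing and input-gradient support."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Network:
    """A plain sequential stack of :class:`~evoaug.nn.layers.Layer` objects.

    ``forward(x, train=True)`` caches intermediates so that ``backward``
    can propagate a loss gradient down to the input; at evaluation time
    dropout is the identity and batch norm uses running statistics, making
    inference a deterministic function of the weights.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Batched evaluation-mode forward pass."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def input_gradient(self, x: np.ndarray, task_index: int = 0) -> np.ndarray:
        """Gradient of ``output[:, task_index]`` w.r.t. the input batch.

        Runs in evaluation mode, so the result is deterministic given the
        weights (dropout off, batch norm frozen).
        """
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        out = self.forward(x, train=False)
        seed = np.zeros_like(out)
        seed[:, task_index] = 1.0
        grad = self.backward(seed)
        return grad[0] if squeeze else grad

    # -- parameters ----------------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_state(self) -> list[list[np.ndarray]]:
        return [layer.get_state() for layer in self.layers]

    def set_state(self, state: list[list[np.ndarray]]) -> None:
        for layer, s in zip(self.layers, state):
            layer.set_state(s)

    def first_conv(self):
        from .layers import Conv1D

        for layer in self.layers:
            if isinstance(layer, Conv1D):
                return layer
        raise ValueError("network has no convolutional layer")
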