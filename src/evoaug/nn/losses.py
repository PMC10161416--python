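"""Training losses returning (scalar loss, gradient w.r.t. predictions).

Binary cross-entropy pairs with sigmoid heads (multi-task binary
classification); mean squared error pairs with linear heads (activity
regression).  Gradients are already averaged over every element.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def bce_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    loss = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    grad = (p - y) / (p * (1.0 - p)) / y.size
    return float(loss), grad


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - y
    loss = np.mean(diff**2)
    grad = 2.0 * diff / y.size
    return float(loss), grad


def loss_for_task(task_kind: str):
    if task_kind == "binary":
        return bce_loss
    if task_kind == "regression":
        return mse_loss
    raise ValueError(f"unknown task_kind {task_kind!r}")
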