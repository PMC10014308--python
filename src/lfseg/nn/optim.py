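"""Optimizers with step learning-rate decay and L2 regularization.

Both optimizers apply L2 regularization as a weight-decay term added to the
gradient (classic formulation), matching how deep-learning toolboxes
implement the ``L2Regularization`` training option.  Bias vectors are
exempt from decay.  Learning-rate schedule: piecewise-constant decay,
``lr = initial_lr * drop_factor ** (epoch // drop_period)``.

Parameters are addressed as ``(layer, key)`` pairs (see
``UNet.parameter_arrays``) so updates survive layers rebinding their
parameter and gradient dicts between steps.
"""

from __future__ import annotations

import numpy as np


class _Optimizer:
    def __init__(self, parameter_arrays, lr: float, weight_decay: float = 0.0) -> None:
        self.parameter_arrays = list(parameter_arrays)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def _gradient(self, layer, key: str) -> np.ndarray:
        g = layer.grads[key]
        if self.weight_decay and key == "W":
            g = g + self.weight_decay * layer.params[key]
        return g

    def step(self) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class SGDMomentum(_Optimizer):
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, parameter_arrays, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        super().__init__(parameter_arrays, lr, weight_decay)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(l.params[k]) for l, k in self.parameter_arrays]

    def step(self) -> None:
        for v, (layer, key) in zip(self._velocity, self.parameter_arrays):
            g = self._gradient(layer, key)
            v *= self.momentum
            v -= self.lr * g
            layer.params[key] = layer.params[key] + v


class Adam(_Optimizer):
    """Adam with bias-corrected first/second moment estimates."""

    def __init__(
        self,
        parameter_arrays,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        super().__init__(parameter_arrays, lr, weight_decay)
        self.beta1, self.beta2, self.eps = float(beta1), float(beta2), float(eps)
        self._m = [np.zeros_like(l.params[k]) for l, k in self.parameter_arrays]
        self._v = [np.zeros_like(l.params[k]) for l, k in self.parameter_arrays]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for m, v, (layer, key) in zip(self._m, self._v, self.parameter_arrays):
            g = self._gradient(layer, key)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[key] = layer.params[key] - self.lr * (m / bc1) / (
                np.sqrt(v / bc2) + self.eps
            )


def step_decay_lr(initial_lr: float, epoch: int, drop_period: int, drop_factor: float) -> float:
    """Learning rate for ``epoch`` (0-based) under piecewise-constant decay."""
    return initial_lr * drop_factor ** (epoch // max(drop_period, 1))
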