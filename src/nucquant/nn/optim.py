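"""Optimizers and the reduce-on-plateau learning-rate schedule.

Both optimizers step over a list of layers, reading ``layer.grads`` written
by the backward pass.  Weight decay is decoupled from the raw gradient
(added as ``wd * param``) and skipped for biases.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "ReduceLROnPlateau"]


class _Optimizer:
    def __init__(self, layers, lr: float, weight_decay: float) -> None:
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.weight_decay = weight_decay

    def _grad(self, layer, name):
        g = layer.grads[name].astype(np.float32)
        if self.weight_decay and name != "b":
            g = g + self.weight_decay * layer.params[name]
        return g

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    """SGD with Nesterov momentum (default 0.9) and weight decay."""

    def __init__(self, layers, lr: float = 0.002, momentum: float = 0.9,
                 nesterov: bool = True, weight_decay: float = 3e-5) -> None:
        super().__init__(layers, lr, weight_decay)
        self.momentum = momentum
        self.nesterov = nesterov
        self._vel = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self._vel):
            for name in layer.params:
                g = self._grad(layer, name)
                v = vel[name]
                v *= self.momentum
                v += g
                update = g + self.momentum * v if self.nesterov else v
                layer.params[name] -= self.lr * update


class Adam(_Optimizer):
    def __init__(self, layers, lr: float = 0.002, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 3e-5) -> None:
        super().__init__(layers, lr, weight_decay)
        self.betas = betas
        self.eps = eps
        self._t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        b1, b2 = self.betas
        self._t += 1
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for name in layer.params:
                g = self._grad(layer, name)
                m[name] = b1 * m[name] + (1 - b1) * g
                v[name] = b2 * v[name] + (1 - b2) * g * g
                mhat = m[name] / bias1
                vhat = v[name] / bias2
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the optimizer's lr by ``factor`` after ``patience`` epochs
    without improvement of the monitored metric.

    ``mode='max'`` for metrics like validation Dice, ``'min'`` for losses.
    """

    def __init__(self, optimizer: _Optimizer, mode: str = "max",
                 factor: float = 0.1, patience: int = 5,
                 min_lr: float = 0.0, threshold: float = 1e-4) -> None:
        if not (0 < factor < 1):
            raise ValueError("factor must lie in (0, 1)")
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best: float | None = None
        self.num_bad = 0

    def _improved(self, value: float) -> bool:
        if self.best is None:
            return True
        if self.mode == "max":
            return value > self.best + self.threshold
        return value < self.best - self.threshold

    def step(self, value: float) -> float:
        """Record one epoch's metric; returns the (possibly reduced) lr."""
        if self._improved(value):
            self.best = value
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor,
                                        self.min_lr)
                self.num_bad = 0
        return self.optimizer.lr
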