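"""First-order optimizers, plateau scheduling, and early stopping."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["SGD", "Adam", "ReduceLROnPlateau", "EarlyStopper"]


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1**self._t
        bc2 = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer learning rate when the watched
    metric has not improved by ``min_delta`` for ``patience`` epochs."""

    def __init__(
        self,
        optimizer,
        factor: float = 0.5,
        patience: int = 10,
        min_delta: float = 1e-5,
        min_lr: float = 1e-6,
    ):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.min_lr = min_lr
        self._best = np.inf
        self._bad = 0

    def step(self, metric: float) -> None:
        if metric < self._best - self.min_delta:
            self._best = metric
            self._bad = 0
        else:
            self._bad += 1
            if self._bad > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self._bad = 0


class EarlyStopper:
    """Stop training when the validation metric stops improving.

    Tracks the best metric seen; ``should_stop`` becomes true after
    ``patience`` consecutive epochs without an improvement of at least
    ``min_delta``. The caller can restore ``best_state`` afterwards.
    """

    def __init__(self, patience: int = 25, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_state: dict | None = None
        self._bad = 0

    def update(self, metric: float, model) -> bool:
        """Record this epoch's metric; returns True when training should stop."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.best_state = model.state_dict()
            self._bad = 0
        else:
            self._bad += 1
        return self._bad >= self.patience
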