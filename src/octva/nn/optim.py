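"""Stochastic gradient descent with momentum and step decay."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD"]


class SGD:
    """Classical momentum SGD.

    The learning rate follows a step schedule: ``lr0 * decay**(epoch //
    step_epochs)``, applied by calling :meth:`set_epoch` at the start of
    each epoch.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 0.01,
        momentum: float = 0.9,
        decay: float = 0.1,
        step_epochs: int = 40,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr0 = lr
        self.lr = lr
        self.momentum = momentum
        self.decay = decay
        self.step_epochs = step_epochs
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def set_epoch(self, epoch: int) -> float:
        self.lr = self.lr0 * self.decay ** (epoch // self.step_epochs)
        return self.lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
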