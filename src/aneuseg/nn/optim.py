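"""Optimizers and learning-rate schedules.

RMSProp (with optional L1/L2 penalties) drives the coarse stage; Adam drives
the fine stage.  Schedules: a step decay that halves the rate at fixed
intervals, a reduce-on-plateau rule that halves after a run of epochs with
no validation improvement, and an early-stopping monitor.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RMSProp", "Adam", "StepDecay", "ReduceLROnPlateau", "EarlyStopping"]


class _Optimizer:
    def __init__(self, params: list, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _reg_grad(self, p):
        g = p.grad
        if g is None:
            return None
        if getattr(self, "l1", 0.0):
            g = g + self.l1 * np.sign(p.data)
        if getattr(self, "l2", 0.0):
            g = g + 2.0 * self.l2 * p.data
        return g


class RMSProp(_Optimizer):
    """RMSProp with optional L1/L2 regularization penalties."""

    def __init__(self, params, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8,
                 l1: float = 0.0, l2: float = 0.0):
        super().__init__(params, lr)
        self.rho, self.eps, self.l1, self.l2 = rho, eps, l1, l2
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self.sq):
            g = self._reg_grad(p)
            if g is None:
                continue
            s *= self.rho
            s += (1.0 - self.rho) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam(_Optimizer):
    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.l1 = self.l2 = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class StepDecay:
    """Multiply the rate by ``factor`` every ``step_epochs`` epochs."""

    def __init__(self, optimizer, step_epochs: int, factor: float = 0.5):
        if step_epochs < 1:
            raise ValueError("step_epochs must be >= 1")
        self.opt = optimizer
        self.step_epochs = step_epochs
        self.factor = factor
        self.epoch = 0

    def step(self) -> float:
        """Advance one epoch; returns the rate in force for the next epoch."""
        self.epoch += 1
        if self.epoch % self.step_epochs == 0:
            self.opt.lr *= self.factor
        return self.opt.lr


class ReduceLROnPlateau:
    """Halve the rate after ``patience`` epochs without improvement.

    ``step(val_loss)`` is called once per epoch; an epoch counts as an
    improvement when the loss falls below the best seen so far by more than
    ``min_delta``. When the no-improvement run reaches ``patience`` the rate
    is multiplied by ``factor`` and the run counter resets.
    """

    def __init__(self, optimizer, patience: int = 10, factor: float = 0.5,
                 min_delta: float = 0.0):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr *= self.factor
                self.bad_epochs = 0
        return self.opt.lr


class EarlyStopping:
    """Signal a stop after ``patience`` epochs without improvement."""

    def __init__(self, patience: int = 50, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> bool:
        """Returns True when training should stop."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience
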