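"""Parameter containers, the batched LSTM runner, dropout, gradient clipping,
and the Adam optimizer."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .autograd import Tensor, stack

__all__ = ["Param", "glorot", "lstm_run", "dropout", "Adam", "clip_gradients"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def lstm_run(
    xs: Tensor,
    W: Tensor,
    U: Tensor,
    b: Tensor,
    hidden: int,
    reverse: bool = False,
) -> Tensor:
    """Run an LSTM over ``xs`` of shape (B, T, D); returns (B, T, H).

    All sequences in a batch share one length (the trainers bucket sentences
    by exact length), so no masking is required.
    """
    B, T, _ = xs.shape
    h = Tensor(np.zeros((B, hidden)))
    c = Tensor(np.zeros((B, hidden)))
    outs: list[Optional[Tensor]] = [None] * T
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        gates = xs[:, t, :] @ W + h @ U + b
        i = gates[:, 0:hidden].sigmoid()
        f = gates[:, hidden : 2 * hidden].sigmoid()
        g = gates[:, 2 * hidden : 3 * hidden].tanh()
        o = gates[:, 3 * hidden : 4 * hidden].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outs[t] = h
    return stack(outs, axis=1)


def dropout(x: Tensor, rate: float, rng: Optional[np.random.Generator]) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (inference) or rate==0."""
    if rng is None or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * Tensor(mask)


def clip_gradients(params: list, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Param(Tensor):
    """Alias kept for readability when declaring model parameters."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
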