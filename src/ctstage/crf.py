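"""Linear-chain CRF written from scratch on numpy.

A path score is ``start[y_0] + sum_t emissions[t, y_t] +
sum_t transitions[y_t, y_{t+1}] + stop[y_{T-1}]``.  The module provides the
log-partition (forward algorithm), Viterbi decoding, and a batched negative
log-likelihood with analytic gradients via forward-backward marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CrfParams",
    "crf_sequence_score",
    "crf_log_partition",
    "viterbi_decode",
    "crf_batch_nll_grad",
    "bio_transition_masks",
]


@dataclass
class CrfParams:
    """Transition scores over a fixed label set plus start/stop scores."""

    transitions: np.ndarray  # (L, L)
    start: np.ndarray  # (L,)
    stop: np.ndarray  # (L,)
    label_set: tuple = ()

    def __post_init__(self):
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.start = np.asarray(self.start, dtype=np.float64)
        self.stop = np.asarray(self.stop, dtype=np.float64)
        L = self.transitions.shape[0]
        if self.transitions.shape != (L, L) or self.start.shape != (L,) or self.stop.shape != (L,):
            raise ValueError("inconsistent CRF parameter shapes")
        if not (
            np.isfinite(self.transitions).all()
            and np.isfinite(self.start).all()
            and np.isfinite(self.stop).all()
        ):
            raise ValueError("CRF parameters must be finite")

    @property
    def n_labels(self) -> int:
        return self.transitions.shape[0]


def _check_emissions(emissions: np.ndarray, params: CrfParams) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (T>=1, L)")
    if emissions.shape[1] != params.n_labels:
        raise ValueError(
            f"emissions have {emissions.shape[1]} labels, params have {params.n_labels}"
        )
    return emissions


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def crf_sequence_score(
    emissions: np.ndarray, labels: Sequence[int], params: CrfParams
) -> float:
    emissions = _check_emissions(emissions, params)
    labels = list(labels)
    if len(labels) != emissions.shape[0]:
        raise ValueError("labels/emissions length mismatch")
    score = params.start[labels[0]] + emissions[0, labels[0]]
    for t in range(1, len(labels)):
        score += params.transitions[labels[t - 1], labels[t]] + emissions[t, labels[t]]
    return float(score + params.stop[labels[-1]])


def crf_log_partition(emissions: np.ndarray, params: CrfParams) -> float:
    """log sum over all label paths of exp(path score) (forward algorithm)."""
    emissions = _check_emissions(emissions, params)
    alpha = params.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _lse(alpha[:, None] + params.transitions, axis=0) + emissions[t]
    return float(_lse(alpha + params.stop, axis=0))


def viterbi_decode(
    emissions: np.ndarray, params: CrfParams
) -> tuple[list[int], float]:
    """Best-scoring label path and its score.

    Ties resolve toward the lowest label index (``argmax`` keeps the first
    maximum at every backtracking step).
    """
    emissions = _check_emissions(emissions, params)
    T, L = emissions.shape
    delta = params.start + emissions[0]
    back = np.zeros((T, L), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + params.transitions  # (from, to)
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + emissions[t]
    final = delta + params.stop
    last = int(final.argmax())
    path = [last]
    for t in range(T - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    path.reverse()
    return path, float(final.max())


def crf_batch_nll_grad(
    emissions: np.ndarray, labels: np.ndarray, params: CrfParams
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Summed negative log-likelihood over a batch of equal-length sequences.

    Returns ``(nll, d_emissions, d_transitions, d_start, d_stop)`` where the
    gradients are expected counts minus gold counts (forward-backward).
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    labels = np.asarray(labels)
    B, T, L = emissions.shape
    trans = params.transitions

    alphas = np.empty((B, T, L))
    alphas[:, 0] = params.start + emissions[:, 0]
    for t in range(1, T):
        # (B, from, to)
        m = alphas[:, t - 1][:, :, None] + trans[None]
        alphas[:, t] = _lse(m, axis=1) + emissions[:, t]
    logZ = _lse(alphas[:, -1] + params.stop, axis=1)  # (B,)

    betas = np.empty((B, T, L))
    betas[:, -1] = params.stop
    for t in range(T - 2, -1, -1):
        m = trans[None] + (emissions[:, t + 1] + betas[:, t + 1])[:, None, :]
        betas[:, t] = _lse(m, axis=2)

    # unary marginals
    marg = np.exp(alphas + betas - logZ[:, None, None])  # (B, T, L)
    d_em = marg.copy()
    bidx = np.arange(B)[:, None]
    tidx = np.arange(T)[None, :]
    d_em[bidx, tidx, labels] -= 1.0

    # pairwise marginals accumulated into the transition gradient
    d_trans = np.zeros_like(trans)
    for t in range(T - 1):
        pair = (
            alphas[:, t][:, :, None]
            + trans[None]
            + (emissions[:, t + 1] + betas[:, t + 1])[:, None, :]
            - logZ[:, None, None]
        )
        d_trans += np.exp(pair).sum(axis=0)
        np.subtract.at(d_trans, (labels[:, t], labels[:, t + 1]), 1.0)

    d_start = marg[:, 0].sum(axis=0)
    np.subtract.at(d_start, labels[:, 0], 1.0)
    d_stop = marg[:, -1].sum(axis=0)
    np.subtract.at(d_stop, labels[:, -1], 1.0)

    gold = params.start[labels[:, 0]] + emissions[bidx, tidx, labels].sum(axis=1)
    if T > 1:
        gold = gold + trans[labels[:, :-1], labels[:, 1:]].sum(axis=1)
    gold = gold + params.stop[labels[:, -1]]
    nll = float((logZ - gold).sum())
    return nll, d_em, d_trans, d_start, d_stop


def bio_transition_masks(labels: Sequence[str], penalty: float = -1e4):
    """Additive masks forbidding invalid BIO transitions during decoding.

    ``I-x`` may only follow ``B-x`` or ``I-x``; it may not start a sequence.
    Returns ``(trans_mask (L, L), start_mask (L,))``.
    """
    L = len(labels)
    trans_mask = np.zeros((L, L))
    start_mask = np.zeros(L)
    for j, lab in enumerate(labels):
        if not lab.startswith("I-"):
            continue
        tname = lab[2:]
        start_mask[j] = penalty
        for i, prev in enumerate(labels):
            if prev not in (f"B-{tname}", f"I-{tname}"):
                trans_mask[i, j] = penalty
    return trans_mask, start_mask
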