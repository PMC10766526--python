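"""Numba kernel for CBOW training with negative sampling.

The trainer predicts a held-out diagnosis from the mean of its context
vectors inside a symmetric window, updating both input (``syn0``) and output
(``syn1``) matrices by SGD on the negative-sampling objective

    log sigma(h . v_w) + sum_neg log sigma(-h . v_neg),

with a linearly decaying learning rate.  Negative targets are drawn from a
unigram^0.75 table with an in-kernel xorshift64* generator, so a fixed seed
gives bit-reproducible single-threaded training.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TABLE_SIZE = 100_000
_MAX_EXP = 6.0


def build_negative_table(counts: np.ndarray) -> np.ndarray:
    """Unigram^0.75 sampling table (word2vec convention)."""
    pow_freq = np.maximum(counts.astype(np.float64), 0.0) ** 0.75
    if pow_freq.sum() == 0:
        pow_freq = np.ones_like(pow_freq)
    cum = np.cumsum(pow_freq / pow_freq.sum())
    table = np.searchsorted(cum, (np.arange(_TABLE_SIZE) + 0.5) / _TABLE_SIZE)
    return table.astype(np.int32)


@njit(cache=True, fastmath=False)
def _xorshift(state):
    x = state
    x ^= x >> 12
    x ^= (x << 25) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 27
    return x & 0xFFFFFFFFFFFFFFFF


@njit(cache=True, fastmath=False)
def _sigmoid(x):
    if x > _MAX_EXP:
        return 1.0
    if x < -_MAX_EXP:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=False)
def train_epochs(
    tokens,  # int32 flat corpus
    offsets,  # int64 sentence boundaries, len n_sent+1
    syn0,  # float64 vocab x d, updated in place
    syn1,  # float64 vocab x d, updated in place
    neg_table,  # int32 sampling table
    window,
    n_neg,
    epochs,
    alpha0,
    alpha_min,
    seed,
):
    """Run all epochs sequentially; returns the summed objective of the
    final epoch (the realized log-likelihood of the training cost)."""
    d = syn0.shape[1]
    n_sent = offsets.shape[0] - 1
    total_steps = (offsets[n_sent] - offsets[0]) * epochs
    state = np.uint64(seed * 2654435761 + 1)
    step = 0
    objective = 0.0
    neu1 = np.zeros(d)
    neu1e = np.zeros(d)
    for ep in range(epochs):
        if ep == epochs - 1:
            objective = 0.0
        for s in range(n_sent):
            lo, hi = offsets[s], offsets[s + 1]
            for c in range(lo, hi):
                alpha = alpha0 - (alpha0 - alpha_min) * (step / total_steps)
                step += 1
                a = c - window
                if a < lo:
                    a = lo
                b = c + window + 1
                if b > hi:
                    b = hi
                cw = (b - a) - 1
                if cw <= 0:
                    continue
                # hidden layer: mean of context input vectors
                for k in range(d):
                    neu1[k] = 0.0
                    neu1e[k] = 0.0
                for j in range(a, b):
                    if j == c:
                        continue
                    w = tokens[j]
                    for k in range(d):
                        neu1[k] += syn0[w, k]
                for k in range(d):
                    neu1[k] /= cw
                center = tokens[c]
                for t in range(n_neg + 1):
                    if t == 0:
                        target = center
                        label = 1.0
                    else:
                        state = _xorshift(state)
                        target = neg_table[state % np.uint64(neg_table.shape[0])]
                        if target == center:
                            continue
                        label = 0.0
                    f = 0.0
                    for k in range(d):
                        f += neu1[k] * syn1[target, k]
                    p = _sigmoid(f)
                    if ep == epochs - 1:
                        objective += np.log(max(p if label == 1.0 else 1.0 - p, 1e-12))
                    g = (label - p) * alpha
                    for k in range(d):
                        neu1e[k] += g * syn1[target, k]
                        syn1[target, k] += g * neu1[k]
                # propagate to each context word (share of the mean)
                for j in range(a, b):
                    if j == c:
                        continue
                    w = tokens[j]
                    for k in range(d):
                        syn0[w, k] += neu1e[k] / cw
    return objective
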