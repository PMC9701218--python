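"""Skip-gram with negative sampling (SGNS) over walk corpora.

Minimal word2vec-style trainer: for every (center, context) pair within a
fixed window, take one gradient step on
``log sigmoid(e_c . o_ctx) + sum_neg log sigmoid(-e_c . o_neg)``
with negatives drawn from the unigram^0.75 distribution and a linearly
decaying learning rate.  Single-threaded and fully deterministic for a
fixed seed (an internal xorshift64* generator drives negative sampling).
The inner loop is numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_sgns", "build_vocab"]


def build_vocab(corpus: list[list[str]]) -> tuple[dict[str, int], np.ndarray]:
    """Map corpus tokens to contiguous ids (first-seen order) with counts."""
    vocab: dict[str, int] = {}
    counts: list[int] = []
    for walk in corpus:
        for tok in walk:
            i = vocab.setdefault(tok, len(vocab))
            if i == len(counts):
                counts.append(0)
            counts[i] += 1
    return vocab, np.asarray(counts, dtype=np.float64)


@njit(cache=False)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=False)
def _train_loop(
    tokens, offsets, W_in, W_out, noise_cum,
    window, negatives, epochs, lr, seed,
):
    total_pairs = 0
    n_walks = offsets.shape[0] - 1
    for w in range(n_walks):
        L = offsets[w + 1] - offsets[w]
        for i in range(L):
            lo = i - window if i - window > 0 else 0
            hi = i + window + 1 if i + window + 1 < L else L
            total_pairs += hi - lo - 1
    total_pairs *= epochs
    state = np.uint64(seed) * np.uint64(2654435761) + np.uint64(88172645463325252)
    done = 0
    V = noise_cum.shape[0]
    d = W_in.shape[1]
    for _ in range(epochs):
        for w in range(n_walks):
            start = offsets[w]
            L = offsets[w + 1] - start
            for i in range(L):
                c = tokens[start + i]
                lo = i - window if i - window > 0 else 0
                hi = i + window + 1 if i + window + 1 < L else L
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = tokens[start + j]
                    alpha = lr * (1.0 - done / total_pairs)
                    if alpha < lr * 1e-4:
                        alpha = lr * 1e-4
                    done += 1
                    # accumulate gradient for the center vector
                    for k in range(negatives + 1):
                        if k == 0:
                            tgt = ctx
                            label = 1.0
                        else:
                            state = _xorshift(state)
                            u = (state >> np.uint64(11)) * (1.0 / 9007199254740992.0)
                            tgt = np.searchsorted(noise_cum, u)
                            if tgt >= V:
                                tgt = V - 1
                            if tgt == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for q in range(d):
                            f += W_in[c, q] * W_out[tgt, q]
                        if f > 6.0:
                            sig = 1.0
                        elif f < -6.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-f))
                        g = (label - sig) * alpha
                        for q in range(d):
                            tmp = W_in[c, q]
                            W_in[c, q] += g * W_out[tgt, q]
                            W_out[tgt, q] += g * tmp


def train_sgns(
    corpus: list[list[str]],
    d: int = 64,
    window: int = 3,
    negatives: int = 5,
    epochs: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train SGNS embeddings; returns node id -> d-vector (input vectors)."""
    if not corpus or all(len(w) == 0 for w in corpus):
        raise ValueError("empty walk corpus")
    vocab, counts = build_vocab(corpus)
    V = len(vocab)
    noise = counts**0.75
    noise_cum = np.cumsum(noise / noise.sum())
    noise_cum[-1] = 1.0
    rng = np.random.default_rng(seed)
    W_in = ((rng.random((V, d)) - 0.5) / d).astype(np.float64)
    W_out = np.zeros((V, d), dtype=np.float64)
    tokens = np.empty(sum(len(w) for w in corpus), dtype=np.int64)
    offsets = np.zeros(len(corpus) + 1, dtype=np.int64)
    pos = 0
    for i, walk in enumerate(corpus):
        for tok in walk:
            tokens[pos] = vocab[tok]
            pos += 1
        offsets[i + 1] = pos
    _train_loop(
        tokens, offsets, W_in, W_out, noise_cum,
        np.int64(window), np.int64(negatives), np.int64(epochs),
        float(lr), np.int64(seed % (2**31)),
    )
    return {tok: W_in[i].copy() for tok, i in vocab.items()}
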