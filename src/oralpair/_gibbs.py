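"""Numba kernels for the collapsed Gibbs LDA sampler.

Token-level collapsed Gibbs: each token's topic assignment z is resampled
from the full conditional

    P(z = k | rest)  ∝  (n_dk + alpha) * (n_kw + eta) / (n_k + V * eta)

with the token's own contribution removed from all counts.  The kernels use
numba's per-thread NumPy RNG; :func:`seed_rng` must be called before the
first sweep of a fit so runs are exactly reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=False)
def init_assignments(doc_ids, word_ids, K, n_dk, n_kw, n_k):
    n_tokens = doc_ids.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        n_dk[doc_ids[i], k] += 1
        n_kw[k, word_ids[i]] += 1
        n_k[k] += 1
    return z


@njit(cache=False)
def sweep(doc_ids, word_ids, z, n_dk, n_kw, n_k, alpha, eta, n_iter):
    n_tokens = doc_ids.shape[0]
    K = n_k.shape[0]
    V = n_kw.shape[1]
    veta = V * eta
    probs = np.empty(K)
    for _ in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k_old = z[i]
            n_dk[d, k_old] -= 1
            n_kw[k_old, w] -= 1
            n_k[k_old] -= 1
            total = 0.0
            for k in range(K):
                p = (n_dk[d, k] + alpha) * (n_kw[k, w] + eta) / (n_k[k] + veta)
                probs[k] = p
                total += p
            u = np.random.random() * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += probs[k]
                if u < acc:
                    k_new = k
                    break
            z[i] = k_new
            n_dk[d, k_new] += 1
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
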