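"""Collapsed-Gibbs sweep kernel for the seeded topic model.

One plain-Python implementation, JIT-compiled with numba when available.
The compiled and interpreted paths execute identical floating-point
operations in identical order, so their outputs are bitwise equal — a test
asserts this.  Randomness enters only through the pre-drawn uniforms ``u``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    njit = None
    HAVE_NUMBA = False


def sweep_py(doc_idx, word_idx, z, n_dk, n_kw, n_k, alpha, beta, u):
    """Resample every token once, in array (document-major) order.

    Standard collapsed conditional
    ``p(z_t = k | .) ∝ (n_dk + α) (n_kw + β) / (n_k + Vβ)``
    with the token's own assignment removed from the counts.
    Counts are updated in place; integer conservation is exact.
    """
    T = doc_idx.shape[0]
    K = n_k.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    for t in range(T):
        d = doc_idx[t]
        w = word_idx[t]
        k = z[t]
        n_dk[d, k] -= 1
        n_kw[k, w] -= 1
        n_k[k] -= 1
        total = 0.0
        for j in range(K):
            total += (n_dk[d, j] + alpha) * (n_kw[j, w] + beta) / (n_k[j] + vbeta)
        r = u[t] * total
        acc = 0.0
        newk = K - 1
        for j in range(K):
            acc += (n_dk[d, j] + alpha) * (n_kw[j, w] + beta) / (n_k[j] + vbeta)
            if r < acc:
                newk = j
                break
        z[t] = newk
        n_dk[d, newk] += 1
        n_kw[newk, w] += 1
        n_k[newk] += 1


if HAVE_NUMBA:
    sweep = njit(cache=True)(sweep_py)
else:  # pragma: no cover
    sweep = sweep_py
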