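"""Low-level surrogate-averaging kernel for the Topographic Consistency Test.

Given per-epoch data and a block of pre-drawn uniforms, builds for every
randomization iteration the average of channel-permuted epochs.  Each
epoch gets a fresh Fisher-Yates permutation derived from the uniforms, so
the numba and pure-numpy implementations consume identical randomness and
produce identical surrogates.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _accumulate_numpy(X: np.ndarray, U: np.ndarray, acc: np.ndarray) -> None:
    n_iter, n_ep, n_swaps = U.shape
    n_ch = X.shape[1]
    m = n_iter * n_ep
    perms = np.tile(np.arange(n_ch), (m, 1))
    Uf = U.reshape(m, n_swaps)
    rows = np.arange(m)
    for i in range(n_ch - 1, 0, -1):
        j = (Uf[:, n_ch - 1 - i] * (i + 1)).astype(np.int64)
        np.minimum(j, i, out=j)
        pi = perms[rows, i].copy()
        perms[rows, i] = perms[rows, j]
        perms[rows, j] = pi
    perms = perms.reshape(n_iter, n_ep, n_ch)
    for e in range(n_ep):
        acc += X[e][perms[:, e, :]]


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _accumulate_numba(X, U, acc):  # pragma: no cover - compiled
        n_iter, n_ep, _ = U.shape
        n_ch, n_s = X.shape[1], X.shape[2]
        perm = np.empty(n_ch, np.int64)
        for k in range(n_iter):
            for e in range(n_ep):
                for c in range(n_ch):
                    perm[c] = c
                for i in range(n_ch - 1, 0, -1):
                    j = int(U[k, e, n_ch - 1 - i] * (i + 1))
                    if j > i:
                        j = i
                    tmp = perm[i]
                    perm[i] = perm[j]
                    perm[j] = tmp
                for c in range(n_ch):
                    r = perm[c]
                    for t in range(n_s):
                        acc[k, c, t] += X[e, r, t]


def permuted_channel_averages(X: np.ndarray, n_iter: int,
                              rng: np.random.Generator,
                              max_chunk_floats: float = 4e7) -> np.ndarray:
    """Mean over epochs of channel-permuted data, per iteration.

    ``X`` is (n_epochs, n_channels, n_samples); returns
    (n_iter, n_channels, n_samples) in float32.  Iterations are processed
    in chunks to bound the memory of the uniform-draw block.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    n_ep, n_ch, n_s = X.shape
    out = np.zeros((n_iter, n_ch, n_s), dtype=np.float32)
    per_iter = n_ep * (n_ch - 1)
    chunk = max(1, int(max_chunk_floats / per_iter))
    start = 0
    while start < n_iter:
        stop = min(start + chunk, n_iter)
        U = rng.random((stop - start, n_ep, n_ch - 1), dtype=np.float32)
        if _HAVE_NUMBA:
            _accumulate_numba(X, U, out[start:stop])
        else:
            _accumulate_numpy(X, U, out[start:stop])
        start = stop
    out /= np.float32(n_ep)
    return out
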