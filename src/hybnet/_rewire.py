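"""Degree-preserving rewiring replicates: numba kernel with pure-Python fallback.

A replicate applies ``nswap`` successful double-edge swaps
((u,v),(x,y) -> (u,x),(v,y), rejected if it would create a self-loop or a
multi-edge) to a copy of the observed graph and records its average
clustering coefficient.  Degrees are invariant under every accepted swap,
so per-node degrees are computed once outside the replicate loop.

The adjacency matrix is stored as row bitsets (uint64 words); per-node
triangle counts come from popcounted row intersections over the edge list,
which keeps dense graphs (e.g. near-clique species clusters at the
percolation distance) tractable for 10,000-replicate null distributions.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly where numba is installed
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_ONE = np.uint64(1)
_S1 = np.uint64(1)
_S2 = np.uint64(2)
_S4 = np.uint64(4)
_S56 = np.uint64(56)
_S6 = np.uint64(6)
_MASK6 = np.uint64(63)


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> _S1) & _M1)
    x = (x & _M2) + ((x >> _S2) & _M2)
    x = (x + (x >> _S4)) & _M4
    return (x * _H01) >> _S56


@njit(cache=True, inline="always")
def _get_bit(adj, i, j):
    return (adj[i, j >> 6] >> (np.uint64(j) & _MASK6)) & _ONE


@njit(cache=True, inline="always")
def _set_bit(adj, i, j):
    adj[i, j >> 6] |= _ONE << (np.uint64(j) & _MASK6)


@njit(cache=True, inline="always")
def _clear_bit(adj, i, j):
    adj[i, j >> 6] &= ~(_ONE << (np.uint64(j) & _MASK6))


@njit(cache=True)
def _avg_clustering_bitset(adj, edges, degrees):
    n = adj.shape[0]
    w = adj.shape[1]
    acc = np.zeros(n, dtype=np.int64)
    for e in range(edges.shape[0]):
        u, v = edges[e, 0], edges[e, 1]
        common = np.uint64(0)
        for word in range(w):
            common += _popcount(adj[u, word] & adj[v, word])
        acc[u] += np.int64(common)
        acc[v] += np.int64(common)
    total = 0.0
    for i in range(n):
        k = degrees[i]
        if k >= 2:
            # acc[i] counts each triangle through i twice
            total += acc[i] / (k * (k - 1))
    return total / n


@njit(cache=True)
def _rewired_cc_samples(adj0, edges0, degrees, n_iter, nswap, seed):
    np.random.seed(seed)
    m = edges0.shape[0]
    out = np.empty(n_iter)
    for r in range(n_iter):
        adj = adj0.copy()
        edges = edges0.copy()
        swaps = 0
        tries = 0
        max_tries = 100 * nswap + 1000
        while swaps < nswap and tries < max_tries:
            tries += 1
            ei = np.random.randint(m)
            ej = np.random.randint(m)
            if ei == ej:
                continue
            u, v = edges[ei, 0], edges[ei, 1]
            x, y = edges[ej, 0], edges[ej, 1]
            if u == x or u == y or v == x or v == y:
                continue
            if _get_bit(adj, u, x) or _get_bit(adj, v, y):
                continue
            _clear_bit(adj, u, v)
            _clear_bit(adj, v, u)
            _clear_bit(adj, x, y)
            _clear_bit(adj, y, x)
            _set_bit(adj, u, x)
            _set_bit(adj, x, u)
            _set_bit(adj, v, y)
            _set_bit(adj, y, v)
            edges[ei, 1] = x
            edges[ej, 0] = v
            swaps += 1
        out[r] = _avg_clustering_bitset(adj, edges, degrees)
    return out


def rewired_cc_samples(
    adj: np.ndarray, edges: np.ndarray, n_iter: int, nswap: int, seed: int
) -> np.ndarray:
    """Average clustering of ``n_iter`` degree-preserving rewired replicates.

    ``adj`` is a boolean (n, n) adjacency matrix, ``edges`` an (m, 2) int
    array of its edges.
    """
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    words = (n + 63) // 64
    bits = np.zeros((n, words), dtype=np.uint64)
    ii, jj = np.nonzero(adj)
    np.bitwise_or.at(bits, (ii, jj >> 6), np.uint64(1) << (jj & 63).astype(np.uint64))
    degrees = adj.sum(axis=1).astype(np.int64)
    return _rewired_cc_samples(
        bits,
        np.ascontiguousarray(edges, dtype=np.int64),
        degrees,
        int(n_iter),
        int(nswap),
        int(seed) % (2**31 - 1),
    )
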