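"""Deterministic global minimum-weight cut (Stoer-Wagner) on a dense
non-negative weight matrix.

Ties in the maximum-adjacency search are broken toward the lowest node
index, which makes the returned cut deterministic.  A numba-compiled kernel
is used when numba is importable; a pure-numpy fallback keeps the package
functional without it.
"""

from __future__ import annotations

import numpy as np


def _stoer_wagner_py(W: np.ndarray) -> tuple[float, np.ndarray]:
    n = W.shape[0]
    W = W.astype(np.float64).copy()
    np.fill_diagonal(W, 0.0)
    # each active supernode i holds a set of original vertices via a chain
    nxt = np.full(n, -1, dtype=np.int64)  # linked list: next original vertex
    tail = np.arange(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    best_w = np.inf
    best_side = np.zeros(n, dtype=bool)
    m = n
    while m > 1:
        # maximum adjacency search over active supernodes
        act_idx = np.flatnonzero(active)
        a = act_idx[0]
        added = np.zeros(n, dtype=bool)
        added[a] = True
        wsum = W[a].copy()
        wsum[~active] = -np.inf
        wsum[a] = -np.inf
        prev = a
        last = a
        for _ in range(m - 1):
            v = int(np.argmax(wsum))
            prev, last = last, v
            cut_of_phase = wsum[v]
            added[v] = True
            wsum += W[v]
            wsum[added] = -np.inf
            wsum[~active] = -np.inf
        s, t = prev, last
        if cut_of_phase < best_w - 1e-15:
            best_w = float(cut_of_phase)
            side = np.zeros(n, dtype=bool)
            v = t
            while v != -1:
                side[v] = True
                v = int(nxt[v])
            best_side = side
        # contract t into s
        W[s] += W[t]
        W[:, s] += W[:, t]
        W[s, s] = 0.0
        active[t] = False
        nxt[tail[s]] = t
        tail[s] = tail[t]
        m -= 1
    return best_w, best_side


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False)
    def _sw_kernel(W):  # type: ignore[no-redef]
        n = W.shape[0]
        nxt = np.full(n, -1, dtype=np.int64)
        tail = np.arange(n)
        active = np.ones(n, dtype=np.bool_)
        best_w = np.inf
        best_side = np.zeros(n, dtype=np.bool_)
        m = n
        while m > 1:
            a = -1
            for i in range(n):
                if active[i]:
                    a = i
                    break
            added = np.zeros(n, dtype=np.bool_)
            added[a] = True
            wsum = np.empty(n, dtype=np.float64)
            for i in range(n):
                wsum[i] = W[a, i] if (active[i] and i != a) else -np.inf
            prev = a
            last = a
            cut_of_phase = 0.0
            for _ in range(m - 1):
                v = -1
                vmax = -np.inf
                for i in range(n):
                    if wsum[i] > vmax:
                        vmax = wsum[i]
                        v = i
                prev = last
                last = v
                cut_of_phase = wsum[v]
                added[v] = True
                for i in range(n):
                    if active[i] and not added[i]:
                        wsum[i] += W[v, i]
                wsum[v] = -np.inf
            s = prev
            t = last
            if cut_of_phase < best_w - 1e-15:
                best_w = cut_of_phase
                for i in range(n):
                    best_side[i] = False
                v = t
                while v != -1:
                    best_side[v] = True
                    v = nxt[v]
            for i in range(n):
                W[s, i] += W[t, i]
                W[i, s] += W[i, t]
            W[s, s] = 0.0
            active[t] = False
            nxt[tail[s]] = t
            tail[s] = tail[t]
            m -= 1
        return best_w, best_side

    def stoer_wagner(W: np.ndarray) -> tuple[float, np.ndarray]:
        Wc = np.ascontiguousarray(W, dtype=np.float64).copy()
        np.fill_diagonal(Wc, 0.0)
        w, side = _sw_kernel(Wc)
        return float(w), np.asarray(side, bool)

except ImportError:  # pragma: no cover
    stoer_wagner = _stoer_wagner_py


def min_cut(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Global min cut of the weighted graph given by symmetric matrix ``W``.

    Returns ``(weight, side)`` where ``side`` is a boolean membership vector
    of one shore of the cut (never empty, never full).
    """
    n = W.shape[0]
    if n < 2:
        raise ValueError("min cut needs at least 2 vertices")
    if n == 2:
        return float(W[0, 1]), np.array([False, True])
    w, side = stoer_wagner(W)
    if not side.any() or side.all():  # pragma: no cover - defensive
        side = np.zeros(n, dtype=bool)
        side[int(np.argmin(W.sum(axis=0)))] = True
        w = float(W[side][:, ~side].sum())
    return w, side
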