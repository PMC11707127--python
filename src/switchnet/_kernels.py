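"""Inner loop of the Louvain local-moving phase.

The kernel operates on the CSR arrays of the modularity operator (null
model already embedded, so move gains are plain sums of entries) and a
pregenerated stack of node-visit orders, one per sweep, which makes the
JIT-compiled path and the pure-Python fallback produce identical
results for the same seed.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every optimizer call
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _local_move_kernel(indptr, indices, data, orders, tolerance):
    """Greedy local moving; returns (comm, converged).

    Each node may join a neighboring community or open a fresh
    singleton when every attachment is negative; equal gains keep the
    current community (stability bias).
    """
    n = orders.shape[1]
    max_sweeps = orders.shape[0]
    comm = np.arange(n)
    next_fresh = n
    # scratch: per-candidate community ids and accumulated weights
    cand_ids = np.empty(n, dtype=np.int64)
    cand_w = np.empty(n, dtype=np.float64)
    converged = False
    for sweep in range(max_sweeps):
        moved = 0
        for vi in range(n):
            v = orders[sweep, vi]
            start = indptr[v]
            stop = indptr[v + 1]
            n_cand = 0
            for p in range(start, stop):
                u = indices[p]
                if u == v:
                    continue
                c = comm[u]
                found = False
                for k in range(n_cand):
                    if cand_ids[k] == c:
                        cand_w[k] += data[p]
                        found = True
                        break
                if not found:
                    cand_ids[n_cand] = c
                    cand_w[n_cand] = data[p]
                    n_cand += 1
            cur = comm[v]
            base = 0.0
            for k in range(n_cand):
                if cand_ids[k] == cur:
                    base = cand_w[k]
                    break
            best_c = cur
            best_w = base
            for k in range(n_cand):
                if cand_w[k] > best_w:
                    best_w = cand_w[k]
                    best_c = cand_ids[k]
            if best_w < 0.0:
                best_c = next_fresh
                best_w = 0.0
            if best_c != cur and best_w - base > tolerance:
                comm[v] = best_c
                if best_c == next_fresh:
                    next_fresh += 1
                moved += 1
        if moved == 0:
            converged = True
            break
    return comm, converged


def _local_move_python(indptr, indices, data, orders, tolerance):
    """Pure-Python mirror of the kernel (used when numba is absent)."""
    n = orders.shape[1]
    comm = np.arange(n)
    next_fresh = n
    converged = False
    for sweep in range(orders.shape[0]):
        moved = 0
        for v in orders[sweep]:
            weights: dict[int, float] = {}
            for p in range(indptr[v], indptr[v + 1]):
                u = indices[p]
                if u != v:
                    c = comm[u]
                    weights[c] = weights.get(c, 0.0) + data[p]
            cur = comm[v]
            base = weights.get(cur, 0.0)
            best_c, best_w = cur, base
            # insertion order of dict matches first-encounter order,
            # mirroring the kernel's candidate scan
            for c, w in weights.items():
                if w > best_w:
                    best_c, best_w = c, w
            if best_w < 0.0:
                best_c, best_w = next_fresh, 0.0
            if best_c != cur and best_w - base > tolerance:
                comm[v] = best_c
                if best_c == next_fresh:
                    next_fresh += 1
                moved += 1
        if moved == 0:
            converged = True
            break
    return comm, converged


def local_move(indptr, indices, data, orders, tolerance):
    if _HAVE_NUMBA:
        return _local_move_kernel(indptr, indices, data,
                                  np.ascontiguousarray(orders), tolerance)
    return _local_move_python(indptr, indices, data, orders, tolerance)
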