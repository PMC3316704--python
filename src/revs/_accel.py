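"""Compiled (numba) branch-and-bound best-subset search.

Same algorithm and answers as the pure-Python search in :mod:`revs.search`
— subsets as bitmasks (the 31-predictor cap keeps every subset in one
int64), per-subset RSS via an in-place Cholesky solve on the centred Gram
matrix, RSS-monotonicity pruning against per-level incumbents, and the
lexicographic tie rule.  Importing this module is optional; when numba is
unavailable the caller falls back to the Python implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _popcount(mask: np.int64) -> int:
    c = 0
    while mask:
        mask &= mask - 1
        c += 1
    return c


@njit(cache=True)
def _lex_smaller(m1: np.int64, m2: np.int64, p: int) -> bool:
    """True if m1's sorted index list precedes m2's lexicographically."""
    for i in range(p):
        b1 = (m1 >> i) & 1
        b2 = (m2 >> i) & 1
        if b1 != b2:
            return b1 == 1
    return False


@njit(cache=True)
def _rss_mask(G, g, tss, mask):
    """RSS of the subset encoded by ``mask`` (centred data, intercept
    implicit); minimum-norm fallback on a singular subdesign."""
    p = G.shape[0]
    k = _popcount(mask)
    if k == 0:
        return tss
    idx = np.empty(k, np.int64)
    j = 0
    for i in range(p):
        if (mask >> i) & 1:
            idx[j] = i
            j += 1
    A = np.empty((k, k))
    b = np.empty(k)
    scale = 0.0
    for r in range(k):
        b[r] = g[idx[r]]
        for c in range(k):
            A[r, c] = G[idx[r], idx[c]]
        if A[r, r] > scale:
            scale = A[r, r]
    # in-place Cholesky, lower triangle
    ok = True
    for i in range(k):
        for j2 in range(i):
            s = A[i, j2]
            for t in range(j2):
                s -= A[i, t] * A[j2, t]
            A[i, j2] = s / A[j2, j2]
        s = A[i, i]
        for t in range(i):
            s -= A[i, t] * A[i, t]
        if s <= 1e-13 * scale:
            ok = False
            break
        A[i, i] = np.sqrt(s)
    if not ok:
        # singular: rebuild and use minimum-norm least squares
        for r in range(k):
            for c in range(k):
                A[r, c] = G[idx[r], idx[c]]
        sol = np.linalg.lstsq(A, b.copy())[0]
        dot = 0.0
        for r in range(k):
            dot += b[r] * sol[r]
        rss = tss - dot
        return rss if rss > 0.0 else 0.0
    # solve L z = b, then L' w = z
    z = np.empty(k)
    for i in range(k):
        s = b[i]
        for t in range(i):
            s -= A[i, t] * z[t]
        z[i] = s / A[i, i]
    w = np.empty(k)
    for i in range(k - 1, -1, -1):
        s = z[i]
        for t in range(i + 1, k):
            s -= A[t, i] * w[t]
        w[i] = s / A[i, i]
    dot = 0.0
    for r in range(k):
        dot += b[r] * w[r]
    rss = tss - dot
    return rss if rss > 0.0 else 0.0


@njit(cache=True)
def _consider(mask, rss, best_rss, best_mask, tol, p):
    k = _popcount(mask)
    if rss < best_rss[k] - tol:
        best_rss[k] = rss
        best_mask[k] = mask
    elif rss <= best_rss[k] + tol:
        if best_mask[k] == 0 or _lex_smaller(mask, best_mask[k], p):
            if rss < best_rss[k]:
                best_rss[k] = rss
            best_mask[k] = mask


@njit(cache=True)
def _branch_and_bound_masks(G, g, tss, tol):
    """Exact per-level best subsets; returns (best_mask, best_rss) arrays
    indexed by level 0..p (level 0 unused)."""
    p = G.shape[0]
    best_rss = np.full(p + 1, np.inf)
    best_mask = np.zeros(p + 1, np.int64)

    # greedy forward selection seeds every level with a strong incumbent
    chosen = np.int64(0)
    for _step in range(p):
        cand_rss = np.inf
        cand_mask = np.int64(0)
        for x in range(p):
            if (chosen >> x) & 1:
                continue
            m = chosen | (np.int64(1) << x)
            r = _rss_mask(G, g, tss, m)
            if r < cand_rss:
                cand_rss = r
                cand_mask = m
        chosen = cand_mask
        _consider(chosen, cand_rss, best_rss, best_mask, tol, p)
    # greedy backward elimination seeds the levels forward may have missed
    pool = np.int64((1 << p) - 1)
    while _popcount(pool) > 1:
        cand_rss = np.inf
        cand_mask = np.int64(0)
        for x in range(p):
            if not (pool >> x) & 1:
                continue
            m = pool & ~(np.int64(1) << x)
            r = _rss_mask(G, g, tss, m)
            if r < cand_rss:
                cand_rss = r
                cand_mask = m
        pool = cand_mask
        _consider(pool, cand_rss, best_rss, best_mask, tol, p)

    # static deletion order: least univariately useful first
    importance = np.empty(p)
    for i in range(p):
        d = G[i, i]
        importance[i] = (g[i] * g[i] / d) if d > 0 else np.inf
    order = np.argsort(importance)

    # iterative DFS; each stack entry is (pool mask, committed mask, rss)
    cap = p * p + 8
    st_pool = np.empty(cap, np.int64)
    st_comm = np.empty(cap, np.int64)
    st_rss = np.empty(cap)
    sp = 0
    full = np.int64((1 << p) - 1)
    full_rss = _rss_mask(G, g, tss, full)
    _consider(full, full_rss, best_rss, best_mask, tol, p)
    st_pool[sp] = full
    st_comm[sp] = np.int64(0)
    st_rss[sp] = full_rss
    sp += 1

    child_rss_buf = np.empty(p)
    child_x_buf = np.empty(p, np.int64)

    while sp > 0:
        sp -= 1
        pool = st_pool[sp]
        comm = st_comm[sp]
        pool_rss = st_rss[sp]
        hi = _popcount(pool) - 1
        lo0 = _popcount(comm)
        if lo0 < 1:
            lo0 = 1
        # re-check at pop time: incumbents may have improved since push
        prunable = True
        for k in range(lo0, hi + 1):
            if pool_rss <= best_rss[k] + tol:
                prunable = False
                break
        if prunable:
            continue
        nchild = 0
        for oi in range(p):
            x = order[oi]
            if not (pool >> x) & 1 or (comm >> x) & 1:
                continue
            # pool_rss lower-bounds every child's rss
            alive = False
            for k in range(lo0, hi + 1):
                if pool_rss <= best_rss[k] + tol:
                    alive = True
                    break
            if not alive:
                break
            child_pool = pool & ~(np.int64(1) << x)
            r = _rss_mask(G, g, tss, child_pool)
            keep = False
            for k in range(lo0, hi + 1):
                if r <= best_rss[k] + tol:
                    keep = True
                    break
            if not keep:
                continue
            _consider(child_pool, r, best_rss, best_mask, tol, p)
            child_rss_buf[nchild] = r
            child_x_buf[nchild] = x
            nchild += 1
        if nchild == 0:
            continue
        # sort children by rss ascending (insertion sort; n <= p)
        for i in range(1, nchild):
            rv = child_rss_buf[i]
            xv = child_x_buf[i]
            j = i - 1
            while j >= 0 and child_rss_buf[j] > rv:
                child_rss_buf[j + 1] = child_rss_buf[j]
                child_x_buf[j + 1] = child_x_buf[j]
                j -= 1
            child_rss_buf[j + 1] = rv
            child_x_buf[j + 1] = xv
        # push in reverse so the least-harmful deletion is explored first;
        # child i commits every variable tried before it
        for i in range(nchild - 1, -1, -1):
            x = child_x_buf[i]
            child_pool = pool & ~(np.int64(1) << x)
            child_comm = comm
            for j in range(i):
                child_comm |= np.int64(1) << child_x_buf[j]
            if _popcount(child_pool) - 1 >= max(_popcount(child_comm), 1):
                st_pool[sp] = child_pool
                st_comm[sp] = child_comm
                st_rss[sp] = child_rss_buf[i]
                sp += 1
    return best_mask, best_rss


def branch_and_bound(G, g, tss, tol):
    """Run the compiled search; returns (best_subset list, best_rss array)
    in the same layout as the Python implementation."""
    p = G.shape[0]
    best_mask, best_rss = _branch_and_bound_masks(
        np.ascontiguousarray(G, dtype=np.float64),
        np.ascontiguousarray(g, dtype=np.float64),
        float(tss),
        float(tol),
    )
    best_subset: list = [None] * (p + 1)
    for k in range(1, p + 1):
        mask = int(best_mask[k])
        best_subset[k] = tuple(i for i in range(p) if (mask >> i) & 1)
    return best_subset, best_rss
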