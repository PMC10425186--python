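"""Compiled inner loop of the greedy peel.

The peel is a strict sequential process — one vertex per step, chosen by
a min-heap keyed on (selection score, vertex index) — so it cannot be
vectorised; instead the loop is JIT-compiled with numba over flat CSR
arrays. Vertex indices follow sorted label order, so comparing indices
is comparing labels and all tie-breaks stay lexicographic. Heaps are
lazy-deletion binary heaps on parallel key/index arrays; an entry is
valid only while it matches the vertex's current score (or weighted
degree), which preserves the amortised O(m log n) bound.

The pure-Python twin of this loop lives in :mod:`usnap.peel`
(``_PeelEngine._run_python``); both produce bit-identical traces and the
test suite asserts so.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["peel_core"]


@njit(cache=True)
def _heap_push(hk, hi, size, key, idx):
    """Push (key, idx) onto the (hk, hi) min-heap; returns new size."""
    pos = size
    hk[pos] = key
    hi[pos] = idx
    while pos > 0:
        parent = (pos - 1) >> 1
        if hk[parent] > hk[pos] or (hk[parent] == hk[pos] and hi[parent] > hi[pos]):
            hk[parent], hk[pos] = hk[pos], hk[parent]
            hi[parent], hi[pos] = hi[pos], hi[parent]
            pos = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(hk, hi, size):
    """Pop the minimum; returns (key, idx, new size)."""
    key = hk[0]
    idx = hi[0]
    size -= 1
    if size > 0:
        hk[0] = hk[size]
        hi[0] = hi[size]
        pos = 0
        while True:
            left = 2 * pos + 1
            if left >= size:
                break
            right = left + 1
            small = left
            if right < size and (
                hk[right] < hk[left] or (hk[right] == hk[left] and hi[right] < hi[left])
            ):
                small = right
            if hk[small] < hk[pos] or (hk[small] == hk[pos] and hi[small] < hi[pos]):
                hk[pos], hk[small] = hk[small], hk[pos]
                hi[pos], hi[small] = hi[small], hi[pos]
                pos = small
            else:
                break
    return key, idx, size


@njit(cache=True)
def peel_core(indptr, nbrs, wts, usp, dead, stop_floor, with_bounds):
    """Run one full peel over the CSR graph, honouring the ``dead`` mask.

    Returns per-configuration arrays (step 0 = starting residual graph):
    removed vertex index (-1 for step 0), vertex / edge / u-specific edge
    counts, mass, and the per-step density bracket (NaN where not
    recorded). The caller derives densities, exclusive fractions and the
    best feasible configuration from these.
    """
    n = dead.shape[0]
    m2 = nbrs.shape[0]

    dw = np.zeros(n, np.float64)
    du = np.zeros(n, np.int64)
    d = np.zeros(n, np.int64)
    mass = 0.0
    n_edges = 0
    n_u = 0
    alive = 0
    for i in range(n):
        if dead[i]:
            continue
        alive += 1
        s = 0.0
        c = 0
        cu = 0
        for p in range(indptr[i], indptr[i + 1]):
            if dead[nbrs[p]]:
                continue
            s += wts[p]
            c += 1
            if usp[p]:
                cu += 1
        dw[i] = s
        d[i] = c
        du[i] = cu
        mass += s
        n_edges += c
        n_u += cu
    mass /= 2.0
    n_edges //= 2
    n_u //= 2

    max_steps = alive + 1
    out_removed = np.full(max_steps, -1, np.int64)
    out_nv = np.zeros(max_steps, np.int64)
    out_ne = np.zeros(max_steps, np.int64)
    out_nu = np.zeros(max_steps, np.int64)
    out_mass = np.zeros(max_steps, np.float64)
    out_lo = np.full(max_steps, np.nan, np.float64)
    out_hi = np.full(max_steps, np.nan, np.float64)
    out_nv[0] = alive
    out_ne[0] = n_edges
    out_nu[0] = n_u
    out_mass[0] = mass
    if alive == 0:
        return (out_removed[:1], out_nv[:1], out_ne[:1], out_nu[:1],
                out_mass[:1], out_lo[:1], out_hi[:1])

    cap = n + m2 // 2 + 4
    score = np.zeros(n, np.float64)
    hk = np.empty(cap, np.float64)
    hidx = np.empty(cap, np.int32)
    hsize = 0
    bk = np.empty(cap if with_bounds else 1, np.float64)
    bidx = np.empty(cap if with_bounds else 1, np.int32)
    bsize = 0
    ik = np.empty(n + 1, np.float64)  # isolated-vertex heap keyed by index
    iidx = np.empty(n + 1, np.int32)
    isize = 0
    for i in range(n):
        if dead[i]:
            continue
        if d[i] == 0:
            isize = _heap_push(ik, iidx, isize, 0.0, i)
        else:
            sc = dw[i] * (1.0 + du[i] / d[i])
            score[i] = sc
            hsize = _heap_push(hk, hidx, hsize, sc, i)
        if with_bounds:
            bsize = _heap_push(bk, bidx, bsize, dw[i], i)

    step = 0
    while alive >= stop_floor and alive >= 2:
        lo = np.nan
        hi = np.nan
        if with_bounds:
            while bsize > 0:
                val = bk[0]
                i = bidx[0]
                if dead[i] == 0 and dw[i] == val:
                    break
                _, _, bsize = _heap_pop(bk, bidx, bsize)
            dw_min = bk[0] if bsize > 0 else 0.0
            denom = alive - 1
            lo = (mass - 2.0 * dw_min) / denom
            hi = (mass - dw_min) / denom

        victim = -1
        while isize > 0:
            _, i, isize = _heap_pop(ik, iidx, isize)
            if dead[i] == 0 and d[i] == 0:
                victim = i
                break
        if victim < 0:
            while hsize > 0:
                sc, i, hsize = _heap_pop(hk, hidx, hsize)
                if dead[i] == 0 and d[i] > 0 and score[i] == sc:
                    victim = i
                    break
        if victim < 0:
            break

        dead[victim] = 1
        for p in range(indptr[victim], indptr[victim + 1]):
            j = nbrs[p]
            if dead[j]:
                continue
            w = wts[p]
            dw[j] -= w
            d[j] -= 1
            mass -= w
            n_edges -= 1
            if usp[p]:
                du[j] -= 1
                n_u -= 1
            if d[j] == 0:
                isize = _heap_push(ik, iidx, isize, 0.0, j)
            else:
                sc = dw[j] * (1.0 + du[j] / d[j])
                score[j] = sc
                hsize = _heap_push(hk, hidx, hsize, sc, j)
            if with_bounds:
                bsize = _heap_push(bk, bidx, bsize, dw[j], j)
        alive -= 1
        step += 1
        out_removed[step] = victim
        out_nv[step] = alive
        out_ne[step] = n_edges
        out_nu[step] = n_u
        out_mass[step] = mass
        out_lo[step] = lo
        out_hi[step] = hi

    k = step + 1
    return (out_removed[:k], out_nv[:k], out_ne[:k], out_nu[:k],
            out_mass[:k], out_lo[:k], out_hi[:k])
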