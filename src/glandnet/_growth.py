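"""Compiled inner loop of the region-growing segmentation.

The growth order is inherently sequential (one brightest-boundary pixel per
iteration), so the loop is JIT-compiled with numba.  The pure-Python mirror
in :mod:`glandnet.segmentation` implements the identical contract and is
used to cross-check this path in the test suite.
"""

import numpy as np
from numba import njit

# state codes
_CB = 1
_CR = 2


@njit(cache=True)
def _heap_less(keys, idxs, a, b):
    # max-heap on intensity; ties broken toward the smaller raster index
    if keys[a] != keys[b]:
        return keys[a] > keys[b]
    return idxs[a] < idxs[b]


@njit(cache=True)
def _heap_push(keys, idxs, size, key, idx):
    i = size
    keys[i] = key
    idxs[i] = idx
    while i > 0:
        parent = (i - 1) // 2
        if _heap_less(keys, idxs, i, parent):
            keys[i], keys[parent] = keys[parent], keys[i]
            idxs[i], idxs[parent] = idxs[parent], idxs[i]
            i = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(keys, idxs, size):
    top_key = keys[0]
    top_idx = idxs[0]
    size -= 1
    keys[0] = keys[size]
    idxs[0] = idxs[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        best = i
        if l < size and _heap_less(keys, idxs, l, best):
            best = l
        if r < size and _heap_less(keys, idxs, r, best):
            best = r
        if best == i:
            break
        keys[i], keys[best] = keys[best], keys[i]
        idxs[i], idxs[best] = idxs[best], idxs[i]
        i = best
    return top_key, top_idx, size


@njit(cache=True)
def grow_flat(vals, mask, sr, sc, r0, r1, c0, c1):
    """Grow from seed (sr, sc) inside box [r0..r1] x [c0..c1].

    Returns (rows, cols, strength): the pixel coordinates of the region at
    the iteration of maximal boundary strength (earliest on ties) and that
    strength.  Boundary strength = mean(IB) - mean(CB) where IB is the set
    of region pixels adjacent to the current boundary CB.
    """
    H, W = vals.shape
    cap = (r1 - r0 + 3) * (c1 - c0 + 3) + 16
    state = np.zeros(H * W, dtype=np.uint8)
    cbn = np.zeros(H * W, dtype=np.int8)   # CB-neighbour count of CR pixels
    keys = np.empty(cap, dtype=np.float64)
    idxs = np.empty(cap, dtype=np.int64)
    heap_size = 0
    cb_sum = 0.0
    cb_cnt = 0
    ib_sum = 0.0
    ib_cnt = 0
    max_iter = (r1 - r0 + 1) * (c1 - c0 + 1)
    order = np.empty(max_iter, dtype=np.int64)
    strengths = np.empty(max_iter, dtype=np.float64)

    seed_idx = sr * W + sc
    state[seed_idx] = _CR
    for dr in range(-1, 2):
        for dc in range(-1, 2):
            if dr == 0 and dc == 0:
                continue
            rr = sr + dr
            cc = sc + dc
            if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] != 0:
                j = rr * W + cc
                if state[j] == 0:
                    state[j] = _CB
                    heap_size = _heap_push(keys, idxs, heap_size, vals[rr, cc], j)
                    cb_sum += vals[rr, cc]
                    cb_cnt += 1
                    cbn[seed_idx] += 1
    if cbn[seed_idx] > 0:
        ib_sum += vals[sr, sc]
        ib_cnt += 1

    n_done = 0
    while heap_size > 0:
        v, idx, heap_size = _heap_pop(keys, idxs, heap_size)
        r = idx // W
        c = idx - r * W
        if r < r0 or r > r1 or c < c0 or c > c1:
            break  # attempted to add a pixel outside the bounding box
        state[idx] = _CR
        cb_sum -= v
        cb_cnt -= 1
        # CR neighbours lose one CB neighbour
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = r + dr
                cc = c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    j = rr * W + cc
                    if state[j] == _CR:
                        cbn[j] -= 1
                        if cbn[j] == 0:
                            ib_sum -= vals[rr, cc]
                            ib_cnt -= 1
        # IB membership of the incorporated pixel: count its current CB
        # neighbours first, then let the CB-extension loop add the rest
        n = 0
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = r + dr
                cc = c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    if state[rr * W + cc] == _CB:
                        n += 1
        cbn[idx] = n
        if n > 0:
            ib_sum += v
            ib_cnt += 1
        # extend CB with unvisited masked neighbours
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = r + dr
                cc = c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    j = rr * W + cc
                    if state[j] == 0 and mask[rr, cc] != 0:
                        state[j] = _CB
                        heap_size = _heap_push(keys, idxs, heap_size,
                                               vals[rr, cc], j)
                        cb_sum += vals[rr, cc]
                        cb_cnt += 1
                        # CR pixels adjacent to this new CB pixel join IB
                        for dr2 in range(-1, 2):
                            for dc2 in range(-1, 2):
                                if dr2 == 0 and dc2 == 0:
                                    continue
                                r2 = rr + dr2
                                c2 = cc + dc2
                                if 0 <= r2 < H and 0 <= c2 < W:
                                    j2 = r2 * W + c2
                                    if state[j2] == _CR:
                                        if cbn[j2] == 0:
                                            ib_sum += vals[r2, c2]
                                            ib_cnt += 1
                                        cbn[j2] += 1
        ib_mean = ib_sum / ib_cnt if ib_cnt > 0 else 0.0
        cb_mean = cb_sum / cb_cnt if cb_cnt > 0 else 0.0
        order[n_done] = idx
        strengths[n_done] = ib_mean - cb_mean
        n_done += 1

    if n_done == 0:
        rows = np.empty(1, dtype=np.int64)
        cols = np.empty(1, dtype=np.int64)
        rows[0] = sr
        cols[0] = sc
        return rows, cols, 0.0
    best = 0
    for t in range(1, n_done):
        if strengths[t] > strengths[best]:
            best = t
    rows = np.empty(best + 2, dtype=np.int64)
    cols = np.empty(best + 2, dtype=np.int64)
    rows[0] = sr
    cols[0] = sc
    for t in range(best + 1):
        rows[t + 1] = order[t] // W
        cols[t + 1] = order[t] - (order[t] // W) * W
    return rows, cols, strengths[best]
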