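"""Numba kernel for quality-guided region-growing phase unwrapping.

The region grows from the highest-quality (highest-magnitude) voxel outward.
Candidates sit in a binary max-heap keyed by their own quality; each popped
voxel is unwrapped by adding the multiple of 2*pi that brings it closest to
the mean of its already-unwrapped 6-neighbours.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _push(heap_q, heap_i, heap_n, q, i):  # pragma: no cover - jitted
    c = heap_n
    heap_q[c] = q
    heap_i[c] = i
    heap_n += 1
    while c > 0:
        p = (c - 1) // 2
        if heap_q[p] < heap_q[c]:
            heap_q[p], heap_q[c] = heap_q[c], heap_q[p]
            heap_i[p], heap_i[c] = heap_i[c], heap_i[p]
            c = p
        else:
            break
    return heap_n


@njit(cache=True)
def _pop(heap_q, heap_i, heap_n):  # pragma: no cover - jitted
    top = heap_i[0]
    heap_n -= 1
    heap_q[0] = heap_q[heap_n]
    heap_i[0] = heap_i[heap_n]
    c = 0
    while True:
        left = 2 * c + 1
        right = left + 1
        b = c
        if left < heap_n and heap_q[left] > heap_q[b]:
            b = left
        if right < heap_n and heap_q[right] > heap_q[b]:
            b = right
        if b == c:
            break
        heap_q[c], heap_q[b] = heap_q[b], heap_q[c]
        heap_i[c], heap_i[b] = heap_i[b], heap_i[c]
        c = b
    return top, heap_n


@njit(cache=True)
def _neighbours(idx, nx, ny, nz, nbr):  # pragma: no cover - jitted
    sx = ny * nz
    sy = nz
    x = idx // sx
    rem = idx - x * sx
    y = rem // sy
    z = rem - y * sy
    cnt = 0
    if x > 0:
        nbr[cnt] = idx - sx
        cnt += 1
    if x < nx - 1:
        nbr[cnt] = idx + sx
        cnt += 1
    if y > 0:
        nbr[cnt] = idx - sy
        cnt += 1
    if y < ny - 1:
        nbr[cnt] = idx + sy
        cnt += 1
    if z > 0:
        nbr[cnt] = idx - 1
        cnt += 1
    if z < nz - 1:
        nbr[cnt] = idx + 1
        cnt += 1
    return cnt


@njit(cache=True)
def _unwrap_core(phase, quality, nx, ny, nz, seed):  # pragma: no cover - jitted
    n_vox = nx * ny * nz
    out = phase.copy()
    visited = np.zeros(n_vox, np.uint8)
    enqueued = np.zeros(n_vox, np.uint8)
    heap_q = np.empty(n_vox, np.float64)
    heap_i = np.empty(n_vox, np.int64)
    heap_n = 0
    nbr = np.empty(6, np.int64)

    visited[seed] = 1
    cnt = _neighbours(seed, nx, ny, nz, nbr)
    for k in range(cnt):
        j = nbr[k]
        enqueued[j] = 1
        heap_n = _push(heap_q, heap_i, heap_n, quality[j], j)

    while heap_n > 0:
        idx, heap_n = _pop(heap_q, heap_i, heap_n)
        if visited[idx]:
            continue
        cnt = _neighbours(idx, nx, ny, nz, nbr)
        s = 0.0
        m = 0
        for k in range(cnt):
            j = nbr[k]
            if visited[j]:
                s += out[j]
                m += 1
        mean = s / m
        out[idx] = phase[idx] + TWO_PI * np.rint((mean - phase[idx]) / TWO_PI)
        visited[idx] = 1
        for k in range(cnt):
            j = nbr[k]
            if not visited[j] and not enqueued[j]:
                enqueued[j] = 1
                heap_n = _push(heap_q, heap_i, heap_n, quality[j], j)

    return out
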