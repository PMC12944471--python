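"""Numba kernel for sliding-window quadratic fits with outlier exclusions.

Windows with no magnitude outliers are handled upstream as a fixed linear
functional of the phase.  Here, each remaining window starts from the
full-window normal equations (Gram matrix A_full and the precomputed
monomial correlations of the phase as right-hand side) and *downdates* them
by the excluded voxels only — far cheaper than rebuilding the 10x10 system
from all kernel voxels.  Only the lower triangle is maintained; each system
is solved by Cholesky, and failure (too few survivors or a non-positive
pivot) yields NaN.
"""

import numpy as np
from numba import njit

_N = 10


@njit(cache=True, fastmath=True)
def _cholesky_solve_lower(A, b, beta):  # pragma: no cover - jitted
    """SPD solve reading the lower triangle of A; False on a bad pivot."""
    L = np.zeros((_N, _N))
    for i in range(_N):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    y = np.zeros(_N)
    for i in range(_N):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    for i in range(_N - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, _N):
            s -= L[k, i] * beta[k]
        beta[i] = s / L[i, i]
    return True


@njit(cache=True, fastmath=True)
def _partial_curvatures(
    magnitude,
    phase,
    pos,
    mu,
    rhs,
    X,
    A_full,
    ex,
    ey,
    ez,
    thr,
    min_support,
):  # pragma: no cover - jitted
    """Curvature 2*(a+b+c) for each partial window.

    pos: (n, 3) window-start corner indices; mu: (n,) window magnitude
    means; rhs: (n, 10) full-window X^T phi; X: (K, 10) design matrix rows
    in C order of the window; A_full: (10, 10) full-window Gram matrix.
    """
    n = pos.shape[0]
    out = np.full(n, np.nan)
    A = np.zeros((_N, _N))
    b = np.zeros(_N)
    beta = np.zeros(_N)
    n_patch = ex * ey * ez
    max_excl = n_patch - min_support
    for w in range(n):
        px, py, pz = pos[w, 0], pos[w, 1], pos[w, 2]
        lo = (1.0 - thr) * mu[w]
        hi = (1.0 + thr) * mu[w]
        for i in range(_N):
            b[i] = rhs[w, i]
            for j in range(i + 1):
                A[i, j] = A_full[i, j]
        n_excl = 0
        k = 0
        for ix in range(ex):
            for iy in range(ey):
                for iz in range(ez):
                    m = magnitude[px + ix, py + iy, pz + iz]
                    if m < lo or m > hi:
                        n_excl += 1
                        p = phase[px + ix, py + iy, pz + iz]
                        for i in range(_N):
                            xi = X[k, i]
                            b[i] -= xi * p
                            for j in range(i + 1):
                                A[i, j] -= xi * X[k, j]
                    k += 1
        if n_excl <= max_excl and _cholesky_solve_lower(A, b, beta):
            out[w] = 2.0 * (beta[0] + beta[1] + beta[2])
    return out
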