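"""Numba kernels for Smith-Waterman/Gotoh local alignment.

Gap model: a gap of length k costs open + k*ext (BLAST convention, so the
default 11/1 scheme charges 12 for a length-1 gap).  Three-state recurrences:

    Ix[i,j] = best score ending with q[i] against a gap   (gap in target)
    Iy[i,j] = best score ending with t[j] against a gap   (gap in query)
    H[i,j]  = max(0, H[i-1,j-1]+s(q_i,t_j), Ix[i,j], Iy[i,j])
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**12)


@njit(cache=False)
def sw_score(q, t, sub, gap_open, gap_ext):
    """Optimal local alignment score (linear memory)."""
    m, n = q.shape[0], t.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    Hprev = np.zeros(n + 1, dtype=np.int64)
    Ix = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        for j in range(n + 1):
            Hprev[j] = H[j]
        H[0] = 0
        Iy = NEG
        for j in range(1, n + 1):
            e = Hprev[j] - gap_open - gap_ext
            if Ix[j] - gap_ext > e:
                e = Ix[j] - gap_ext
            Ix[j] = e
            f = H[j - 1] - gap_open - gap_ext
            if Iy - gap_ext > f:
                f = Iy - gap_ext
            Iy = f
            h = Hprev[j - 1] + sub[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=False)
def sw_fill(q, t, sub, gap_open, gap_ext):
    """Full DP matrices (H, Ix, Iy) for traceback."""
    m, n = q.shape[0], t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i - 1, j] - gap_open - gap_ext
            if Ix[i - 1, j] - gap_ext > e:
                e = Ix[i - 1, j] - gap_ext
            Ix[i, j] = e
            f = H[i, j - 1] - gap_open - gap_ext
            if Iy[i, j - 1] - gap_ext > f:
                f = Iy[i, j - 1] - gap_ext
            Iy[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, Ix, Iy
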