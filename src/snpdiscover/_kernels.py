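"""Numerical kernel for gapped x-drop extension (banded affine DP).

The extension explores a fixed diagonal band around the seed diagonal and
abandons a path once its score falls more than ``xdrop`` below the best
score seen so far; the reported endpoint is the maximum-score cell, so a
trailing mismatch never lengthens an overlap.  Gap of length g costs
gap_open + g * gap_extend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def xdrop_extend_kernel(a, b, match, mismatch, gap_open, gap_extend, xdrop, bw):
    """Extend an alignment forward from (0, 0) over codes ``a`` and ``b``.

    Returns (best_i, best_j, best_score, ops) where ops (reversed order,
    trimmed) encodes the traceback from the best cell back to the origin:
    0 = diagonal, 1 = gap in a (consumes b), 2 = gap in b (consumes a).
    """
    la = len(a)
    lb = len(b)
    width = 2 * bw + 1
    rows = la + 1
    H = np.full((rows, width), NEG, dtype=np.int64)
    E = np.full((rows, width), NEG, dtype=np.int64)
    F = np.full((rows, width), NEG, dtype=np.int64)
    tbH = np.zeros((rows, width), dtype=np.int8)  # 0 diag,1 E,2 F,3 origin
    tbE = np.zeros((rows, width), dtype=np.int8)  # 0 from H, 1 from E
    tbF = np.zeros((rows, width), dtype=np.int8)

    H[0, bw] = 0
    tbH[0, bw] = 3
    best = 0
    best_i = 0
    best_k = bw
    for k in range(bw + 1, width):
        j = k - bw
        if j > lb:
            break
        e = -gap_open - j * gap_extend
        E[0, k] = e
        tbE[0, k] = 1 if j > 1 else 0
        H[0, k] = e
        tbH[0, k] = 1

    for i in range(1, rows):
        row_best = NEG
        any_alive = False
        for k in range(width):
            j = i + k - bw
            if j < 0 or j > lb:
                continue
            # F: gap in b (consumes a), from row i-1, band column k+1
            f = NEG
            if k + 1 < width:
                fo = H[i - 1, k + 1] - gap_open - gap_extend
                fe = F[i - 1, k + 1] - gap_extend
                if fo >= fe:
                    f = fo
                    tbF[i, k] = 0
                else:
                    f = fe
                    tbF[i, k] = 1
            F[i, k] = f
            # E: gap in a (consumes b), from same row, band column k-1
            e = NEG
            if k - 1 >= 0 and j >= 1:
                eo = H[i, k - 1] - gap_open - gap_extend
                ee = E[i, k - 1] - gap_extend
                if eo >= ee:
                    e = eo
                    tbE[i, k] = 0
                else:
                    e = ee
                    tbE[i, k] = 1
            E[i, k] = e
            # H
            d = NEG
            if j >= 1:
                prev = H[i - 1, k]
                if prev > NEG // 2:
                    s = match if a[i - 1] == b[j - 1] else -mismatch
                    d = prev + s
            h = d
            t = 0
            if e > h:
                h = e
                t = 1
            if f > h:
                h = f
                t = 2
            if h < best - xdrop:
                h = NEG  # x-drop prune
            else:
                any_alive = True
            H[i, k] = h
            tbH[i, k] = t
            if h > row_best:
                row_best = h
            if h > best:
                best = h
                best_i = i
                best_k = k
        if not any_alive:
            break

    # traceback
    ops = np.empty(la + lb + 1, dtype=np.int8)
    n = 0
    i = best_i
    k = best_k
    state = 0  # 0 in H, 1 in E, 2 in F
    while True:
        if state == 0:
            t = tbH[i, k]
            if t == 3:
                break
            if t == 0:
                ops[n] = 0
                n += 1
                i -= 1
            elif t == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            t = tbE[i, k]
            ops[n] = 1
            n += 1
            k -= 1
            if t == 0:
                state = 0
        else:
            t = tbF[i, k]
            ops[n] = 2
            n += 1
            i -= 1
            k += 1
            if t == 0:
                state = 0
        if i == 0 and k == bw and state == 0 and tbH[0, bw] == 3:
            break
    best_j = best_i + best_k - bw
    return best_i, best_j, best, ops[:n]
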