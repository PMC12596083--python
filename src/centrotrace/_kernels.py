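"""Numba kernels: banded affine-gap local alignment DP and the gapless probe scan.

Bases are 2-bit encoded (A=0, C=1, G=2, T=3); code 4 marks N/ambiguous and
never matches anything.  A gap of length g costs ``gap_open + g * gap_ext``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)

# traceback codes for the H state
PTR_STOP = 0
PTR_DIAG = 1
PTR_E = 2  # gap in query (consumes target)
PTR_F = 3  # gap in target (consumes query)


@njit(fastmath=False)
def banded_sw(q, t, lo, hi, mask, match, mismatch, gap_open, gap_ext):
    """Smith-Waterman (Gotoh affine gaps) restricted to diagonals j-i in [lo, hi].

    ``mask[j]`` forbids any alignment column that consumes target base j
    (used for iterative extraction of multiple hits).  Returns the best
    score, its DP end cell (i, j; 1-based), and the three pointer matrices
    for traceback.  Cell (i, j) is stored at row i, width index
    ``j - (i + lo) + 1``.  Tie-break on equal score: smaller target end j,
    then smaller query end i.
    """
    n = q.shape[0]
    m = t.shape[0]
    W = hi - lo + 1
    ptrH = np.zeros((n + 1, W + 2), dtype=np.int8)
    ptrE = np.zeros((n + 1, W + 2), dtype=np.int8)
    ptrF = np.zeros((n + 1, W + 2), dtype=np.int8)

    H_prev = np.full(W + 2, NEG, dtype=np.int64)
    F_prev = np.full(W + 2, NEG, dtype=np.int64)
    H_cur = np.full(W + 2, NEG, dtype=np.int64)
    E_cur = np.full(W + 2, NEG, dtype=np.int64)
    F_cur = np.full(W + 2, NEG, dtype=np.int64)

    # row 0: H = 0 on valid cells (local alignment can start anywhere)
    j0min = max(1, 0 + lo)
    j0max = min(m, 0 + hi)
    for j in range(j0min, j0max + 1):
        w = j - (0 + lo) + 1
        H_prev[w] = 0
    # also the (0,0) origin if in band
    if lo <= 0 <= hi:
        H_prev[0 - lo + 1] = 0

    best = 0
    best_i = 0
    best_j = 0

    for i in range(1, n + 1):
        for w in range(W + 2):
            H_cur[w] = NEG
            E_cur[w] = NEG
            F_cur[w] = NEG
        jmin = max(1, i + lo)
        jmax = min(m, i + hi)
        qc = q[i - 1]
        for j in range(jmin, jmax + 1):
            w = j - (i + lo) + 1
            tc = t[j - 1]
            masked = mask[j - 1]

            # E: gap in query, consumes t[j-1]; comes from (i, j-1) = w-1 same row
            e = NEG
            if not masked:
                open_e = H_cur[w - 1] - gap_open - gap_ext
                ext_e = E_cur[w - 1] - gap_ext
                if open_e >= ext_e:
                    e = open_e
                    ptrE[i, w] = 1
                else:
                    e = ext_e
                    ptrE[i, w] = 0
            E_cur[w] = e

            # F: gap in target, consumes q[i-1]; comes from (i-1, j) = w+1 prev row
            open_f = H_prev[w + 1] - gap_open - gap_ext
            ext_f = F_prev[w + 1] - gap_ext
            if open_f >= ext_f:
                f = open_f
                ptrF[i, w] = 1
            else:
                f = ext_f
                ptrF[i, w] = 0
            F_cur[w] = f

            # diagonal: consumes both; (i-1, j-1) = same w in prev row
            d = NEG
            if not masked and H_prev[w] >= 0:
                if qc == tc and qc < 4:
                    d = H_prev[w] + match
                else:
                    d = H_prev[w] + mismatch

            # H: preference diag > E > F > stop
            h = 0
            p = PTR_STOP
            if d >= h and d >= e and d >= f:
                if d > 0:
                    h = d
                    p = PTR_DIAG
            elif e >= f:
                if e > 0:
                    h = e
                    p = PTR_E
            else:
                if f > 0:
                    h = f
                    p = PTR_F
            H_cur[w] = h
            ptrH[i, w] = p

            if h > best or (h == best and h > 0 and
                            (j < best_j or (j == best_j and i < best_i))):
                best = h
                best_i = i
                best_j = j

        for w in range(W + 2):
            H_prev[w] = H_cur[w]
            F_prev[w] = F_cur[w]

    return best, best_i, best_j, ptrH, ptrE, ptrF


@njit
def probe_scan(t, p, max_mm):
    """Mismatch count of gapless probe placement at every target start.

    Returns an int32 array of length ``len(t) - len(p) + 1`` holding the
    mismatch count, or ``max_mm + 1`` where the count exceeds the cap
    (inner loop aborts early).  N (code 4) never matches.
    """
    m = t.shape[0]
    k = p.shape[0]
    npos = m - k + 1
    if npos <= 0:
        return np.empty(0, dtype=np.int32)
    out = np.empty(npos, dtype=np.int32)
    for i in range(npos):
        mm = 0
        for j in range(k):
            tc = t[i + j]
            pc = p[j]
            if tc != pc or tc >= 4:
                mm += 1
                if mm > max_mm:
                    break
        out[i] = mm
    return out
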