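"""Independent brute-force oracles for the test suite.

The local-alignment oracle is a full-matrix affine-gap Smith-Waterman with
iterative best-first extraction and target masking — no seeding, no
banding, no windows — sharing only the scoring convention and tie-break
rules with the package aligner.  Bin scoring and probe counting oracles
are naive per-position scans.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from centrotrace.align import AlignmentHit, encode, revcomp

NEG = -(10 ** 9)


@njit
def _full_gotoh(q, t, mask, match, mismatch, gap_open, gap_ext):
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)   # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 opened
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            masked = mask[j - 1]
            e = NEG
            if not masked:
                open_e = H[i, j - 1] - gap_open - gap_ext
                ext_e = E[i, j - 1] - gap_ext
                if open_e >= ext_e:
                    e = open_e
                    ptrE[i, j] = 1
                else:
                    e = ext_e
            E[i, j] = e
            open_f = H[i - 1, j] - gap_open - gap_ext
            ext_f = F[i - 1, j] - gap_ext
            if open_f >= ext_f:
                f = open_f
                ptrF[i, j] = 1
            else:
                f = ext_f
            F[i, j] = f
            d = NEG
            if not masked:
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    d = H[i - 1, j - 1] + match
                else:
                    d = H[i - 1, j - 1] + mismatch
            h = 0
            p = 0
            if d >= h and d >= e and d >= f:
                if d > 0:
                    h = d
                    p = 1
            elif e >= f:
                if e > 0:
                    h = e
                    p = 2
            else:
                if f > 0:
                    h = f
                    p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best or (h == best and h > 0
                            and (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, ptrE, ptrF


def _trace(ptr, ptrE, ptrF, i, j, q, t):
    cols = matches = 0
    qe, te = i, j
    state = 0
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            cols += 1
            opened = ptrE[i, j]
            j -= 1
            if opened:
                state = 0
        else:
            cols += 1
            opened = ptrF[i, j]
            i -= 1
            if opened:
                state = 0
    return i, qe, j, te, cols, matches


def oracle_local_align(query: str, target: str, min_len: int,
                       min_identity: float, query_id: str = "query",
                       target_chrom: str = "target") -> list[AlignmentHit]:
    """All qualifying local alignments by exhaustive DP, both strands."""
    stop_score = max(1, math.ceil((2 * min_identity - 1) * min_len))
    tcodes = encode(target)
    qlen = len(query)
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qcodes = encode(qseq)
        mask = np.zeros(len(tcodes), dtype=np.bool_)
        while True:
            best, bi, bj, ptr, ptrE, ptrF = _full_gotoh(
                qcodes, tcodes, mask, 1, -1, 2, 1)
            if best < stop_score:
                break
            qs, qe, ts, te, cols, matches = _trace(ptr, ptrE, ptrF, bi, bj,
                                                   qcodes, tcodes)
            if te <= ts:
                break
            mask[ts:te] = True
            if cols >= min_len and matches / cols >= min_identity:
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(AlignmentHit(query_id, qs, qe, target_chrom,
                                         ts, te, strand, cols, matches,
                                         int(best)))
    # same duplicate / overlap resolution as the implementation contract:
    # palindromic duplicates keep '+', >=90% same-strand overlaps keep best
    seen: dict[tuple, AlignmentHit] = {}
    for h in sorted(hits, key=lambda h: h.strand):
        key = (h.target_start, h.target_end, h.query_start, h.query_end)
        if key not in seen:
            seen[key] = h
    kept: list[AlignmentHit] = []
    for h in sorted(seen.values(), key=lambda h: -h.score):
        drop = False
        for k in kept:
            if k.strand == h.strand:
                ov = max(0, min(k.target_end, h.target_end)
                         - max(k.target_start, h.target_start))
                shorter = min(k.target_end - k.target_start,
                              h.target_end - h.target_start)
                if shorter and ov / shorter >= 0.9:
                    drop = True
                    break
        if not drop:
            kept.append(h)
    kept.sort(key=lambda h: (h.target_chrom, h.target_start, h.strand))
    return kept


def oracle_bin_scores(query_len: int, hits, bin_width: int):
    """Per-position brute-force (L, N, S) per bin."""
    nbins = max(1, (query_len + bin_width - 1) // bin_width)
    out = []
    for b in range(nbins):
        lo = b * bin_width
        hi = min(query_len, lo + bin_width)
        L = sum(1 for pos in range(lo, hi)
                if any(h.query_start <= pos < h.query_end for h in hits))
        N = sum(1 for h in hits
                if h.query_start < hi and h.query_end > lo)
        out.append((L, N, L * N))
    return out


def oracle_probe_count(probe: str, target: str, max_mm: int) -> int:
    """Naive gapless both-strand scan with best-start overlap collapse."""
    plen = len(probe)
    cands = []
    for strand_seq in (probe, revcomp(probe)):
        for s in range(len(target) - plen + 1):
            mm = sum(1 for a, b in zip(strand_seq, target[s:s + plen].upper())
                     if a.upper() != b or b not in "ACGT")
            if mm <= max_mm:
                cands.append((mm, s))
    best_at: dict[int, int] = {}
    for mm, s in cands:
        if s not in best_at or mm < best_at[s]:
            best_at[s] = mm
    accepted: list[int] = []
    for s in sorted(best_at, key=lambda s: (best_at[s], s)):
        if all(abs(s - a) >= plen for a in accepted):
            accepted.append(s)
    return len(accepted)


def oracle_overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))
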