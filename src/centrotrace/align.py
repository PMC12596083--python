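"""Seed-and-extend local alignment and the binned S = L × N alignment score.

The aligner finds local alignments of a query against a genome on both
strands: exact 13-mer seeds are looked up in a sorted k-mer index, clustered
into candidate windows, and each window is resolved by a banded affine-gap
Smith-Waterman (numba kernel).  Hits within a window are extracted
iteratively, best first, masking the consumed target bases, so reported hits
never overlap on the target.  Scoring: match +1, mismatch −1, gap open −2,
gap extend −1 (a gap of length g costs 2 + g).  Lowercase bases align as
their uppercase equivalents; N never matches.

The binned score follows S = L × N per query bin: L is the number of bin
positions covered by the union of hit query intervals (≤ bin width) and N
the number of hits intersecting the bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._kernels import PTR_DIAG, PTR_E, PTR_F, PTR_STOP, banded_sw
from .io import GenomeSequence

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit-encode a DNA string (A=0 C=1 G=2 T=3, anything else 4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2   # cost; gap of length g costs gap_open + g*gap_ext
    gap_ext: int = 1


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentHit:
    """One local alignment of a query element against the genome.

    ``query_start``/``query_end`` are always on the forward query, also for
    minus-strand hits.  ``L`` (aligned length) is the number of alignment
    columns and ``I`` the column identity — the two factors of the
    identity-weighted mass L·I used by the enrichment index.
    """

    query_id: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    aligned_cols: int
    matches: int
    score: int = 0

    @property
    def L(self) -> int:
        return self.aligned_cols

    @property
    def I(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0


@dataclass
class BinnedScoreTrack:
    """Per-bin (L, N, S) over a query sequence, S = L × N."""

    query_id: str
    bin_width: int
    L: np.ndarray
    N: np.ndarray
    S: np.ndarray

    @property
    def bins(self) -> list[tuple[int, int, int]]:
        return list(zip(self.L.tolist(), self.N.tolist(), self.S.tolist()))

    @property
    def n_bins(self) -> int:
        return len(self.S)


class GenomeIndex:
    """Sorted exact k-mer index over a set of chromosomes.

    Build once per genome; ``local_align`` accepts it in place of the raw
    sequence list to amortize indexing across many queries.
    """

    def __init__(self, genome: Sequence[GenomeSequence] | GenomeSequence,
                 k: int = 13):
        if isinstance(genome, GenomeSequence):
            genome = [genome]
        self.k = k
        self.chroms: dict[str, np.ndarray] = {}
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for gs in genome:
            codes = encode(gs.sequence)
            self.chroms[gs.chrom_id] = codes
            if len(codes) < k:
                self._sorted[gs.chrom_id] = (
                    np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
                continue
            kcodes = _kmer_codes(codes, k)
            valid = _kmer_valid(codes, k)
            kcodes = np.where(valid, kcodes, -1)
            order = np.argsort(kcodes, kind="stable")
            self._sorted[gs.chrom_id] = (kcodes[order], order.astype(np.int64))

    def lookup(self, qcodes: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Seed positions for a query: chrom -> (query_pos, target_pos)."""
        k = self.k
        if len(qcodes) < k:
            return {}
        qk = _kmer_codes(qcodes, k)
        qvalid = _kmer_valid(qcodes, k)
        qpos_all = np.nonzero(qvalid)[0]
        qk = qk[qpos_all]
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (skeys, spos) in self._sorted.items():
            if len(skeys) == 0 or len(qk) == 0:
                continue
            lo = np.searchsorted(skeys, qk, side="left")
            hi = np.searchsorted(skeys, qk, side="right")
            counts = hi - lo
            nz = np.nonzero(counts)[0]
            if len(nz) == 0:
                continue
            qrep = np.repeat(qpos_all[nz], counts[nz])
            tpos = np.concatenate([spos[lo[i]:hi[i]] for i in nz])
            out[chrom] = (qrep, tpos)
        return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.int64)
    c = np.where(codes < 4, codes, 0).astype(np.int64)
    for j in range(k):
        out = out * 4 + c[j:j + n]
    return out


def _kmer_valid(codes: np.ndarray, k: int) -> np.ndarray:
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    n = len(codes) - k + 1
    return (cs[k:] - cs[:n]) == 0


def _cluster_seeds(qpos: np.ndarray, tpos: np.ndarray, qlen: int,
                   gap_break: int,
                   diag_gap: int = 32) -> list[tuple[int, int]]:
    """Group seeds into candidate bands: (dmin, dmax) diagonal ranges.

    Seeds are grouped while both the diagonal jump stays within diag_gap
    (one alignment cannot drift across diagonals faster than its indels)
    and the target jump within gap_break.  Returns per-cluster diagonal
    extents; the window itself is derived from them.
    """
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    tpos = tpos[order]
    qpos = qpos[order]
    diag = diag[order]
    clusters = []
    start = 0
    for i in range(1, len(tpos) + 1):
        if (i == len(tpos)
                or diag[i] - diag[i - 1] > diag_gap
                or abs(int(tpos[i]) - int(tpos[i - 1])) > gap_break):
            qs = qpos[start:i]
            clusters.append((int(diag[start]), int(diag[i - 1]),
                             int(qs.min()), int(qs.max())))
            start = i
    return clusters


def _traceback(ptrH, ptrE, ptrF, i, j, lo, q, t):
    """Walk the pointer matrices from DP cell (i, j); return hit geometry."""
    cols = 0
    matches = 0
    qe, te = i, j
    state = "H"
    while True:
        w = j - (i + lo) + 1
        if state == "H":
            p = ptrH[i, w]
            if p == PTR_STOP:
                break
            if p == PTR_DIAG:
                cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == PTR_E:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1  # gap in query, consumes t[j-1]
            opened = ptrE[i, w]
            j -= 1
            if opened:
                state = "H"
        else:
            cols += 1  # gap in target, consumes q[i-1]
            opened = ptrF[i, w]
            i -= 1
            if opened:
                state = "H"
    return i, qe, j, te, cols, matches


def _align_window(qcodes: np.ndarray, tcodes: np.ndarray, lo: int, hi: int,
                  min_len: int, min_identity: float,
                  scoring: Scoring) -> list[tuple]:
    """Iteratively extract hits in one window; returns window-local tuples."""
    stop_score = max(1, math.ceil((2 * min_identity - 1) * min_len))
    mask = np.zeros(len(tcodes), dtype=np.bool_)
    hits = []
    while True:
        best, bi, bj, ptrH, ptrE, ptrF = banded_sw(
            qcodes, tcodes, lo, hi, mask,
            scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_ext)
        if best < stop_score:
            break
        qs, qe, ts, te, cols, matches = _traceback(
            ptrH, ptrE, ptrF, bi, bj, lo, qcodes, tcodes)
        if te <= ts:  # degenerate (should not happen with positive score)
            break
        mask[ts:te] = True
        if cols >= min_len and matches / cols >= min_identity:
            hits.append((qs, qe, ts, te, cols, matches, int(best)))
    return hits


_MAX_WINDOW_CELLS = 200_000_000


def local_align(
    query: str,
    targets: GenomeIndex | Sequence[GenomeSequence] | GenomeSequence | str,
    min_len: int = 20,
    min_identity: float = 0.8,
    *,
    query_id: str = "query",
    scoring: Scoring = DEFAULT_SCORING,
    band_pad: int = 16,
) -> list[AlignmentHit]:
    """All local alignments of *query* against the targets, both strands.

    Hits satisfy ``aligned_cols >= min_len`` and identity ``>= min_identity``
    and never overlap on the target within a strand (greedy best-first
    extraction).  Deterministic ordering: (target_chrom, target_start,
    strand).
    """
    if not query:
        raise ValueError("query must be non-empty")
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must lie in (0, 1]")
    if isinstance(targets, str):
        targets = [GenomeSequence("target", targets)]
    if not isinstance(targets, GenomeIndex):
        index = GenomeIndex(targets, k=min(13, max(4, min(min_len, len(query)))))
    else:
        index = targets

    qlen = len(query)
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qcodes = encode(qseq)
        seeds = index.lookup(qcodes)
        gap_break = max(500, qlen)
        for chrom, (qpos, tpos) in seeds.items():
            tcodes = index.chroms[chrom]
            m = len(tcodes)
            ext = max(4 * min_len, 120)  # extension allowance beyond seeds
            for dmin, dmax, qmin, qmax in _cluster_seeds(
                    qpos, tpos, qlen, gap_break, diag_gap=2 * band_pad):
                qlo = max(0, qmin - ext)
                qhi = min(qlen, qmax + index.k + ext)
                wstart = max(0, dmin + qlo - band_pad)
                wend = min(m, dmax + qhi + index.k + band_pad)
                lo = dmin + qlo - wstart - band_pad
                hi = dmax + qlo - wstart + band_pad + index.k
                nrows = qhi - qlo
                lo = max(lo, -nrows)
                hi = min(hi, wend - wstart)
                W = hi - lo + 1
                if (nrows + 1) * (W + 2) > _MAX_WINDOW_CELLS:
                    raise MemoryError(
                        f"alignment window too large ({nrows} x {W})")
                win = tcodes[wstart:wend]
                for qs, qe, ts, te, cols, matches, score in _align_window(
                        qcodes[qlo:qhi], win, lo, hi, min_len, min_identity,
                        scoring):
                    qs, qe = qs + qlo, qe + qlo
                    if strand == "-":
                        qs, qe = qlen - qe, qlen - qs
                    hits.append(AlignmentHit(
                        query_id, qs, qe, chrom,
                        wstart + ts, wstart + te, strand, cols, matches,
                        score))
    # a reverse-palindromic query yields the identical alignment on both
    # strands; keep only the '+' copy of exact coordinate duplicates
    seen: dict[tuple, AlignmentHit] = {}
    for h in sorted(hits, key=lambda h: h.strand):
        key = (h.target_chrom, h.target_start, h.target_end,
               h.query_start, h.query_end)
        if key not in seen:
            seen[key] = h
    hits = _suppress_overlaps(list(seen.values()))
    hits.sort(key=lambda h: (h.target_chrom, h.target_start, h.strand))
    return hits


def _suppress_overlaps(hits: list[AlignmentHit],
                       frac: float = 0.9) -> list[AlignmentHit]:
    """Merge same-strand hits whose target spans overlap ≥ frac of the shorter."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if (k.target_chrom == h.target_chrom and k.strand == h.strand):
                ov = max(0, min(k.target_end, h.target_end)
                         - max(k.target_start, h.target_start))
                shorter = min(k.target_end - k.target_start,
                              h.target_end - h.target_start)
                if shorter > 0 and ov / shorter >= frac:
                    redundant = True
                    break
        if not redundant:
            kept.append(h)
    return kept


def bin_scores(query_len: int, hits: Iterable[AlignmentHit],
               bin_width: int) -> BinnedScoreTrack:
    """Partition the query into bins and score each as S = L × N.

    For bin b: N_b counts hits whose query interval intersects b, L_b is
    the number of positions of b covered by the union of hit query
    intervals, and S_b = L_b × N_b.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hits = list(hits)
    qid = hits[0].query_id if hits else "query"
    nbins = max(1, math.ceil(query_len / bin_width))
    covered = np.zeros(query_len, dtype=bool)
    N = np.zeros(nbins, dtype=np.int64)
    for h in hits:
        if not (0 <= h.query_start < h.query_end <= query_len):
            raise ValueError(
                f"hit query interval [{h.query_start},{h.query_end}) outside "
                f"[0,{query_len})")
        covered[h.query_start:h.query_end] = True
        b0 = h.query_start // bin_width
        b1 = (h.query_end - 1) // bin_width
        N[b0:b1 + 1] += 1
    pos = np.nonzero(covered)[0]
    L = np.bincount(pos // bin_width, minlength=nbins).astype(np.int64)
    return BinnedScoreTrack(qid, bin_width, L, N, L * N)
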