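"""Tandem-repeat detection, the centromeric TR catalog, and origin tracing.

The detector is a period-agreement scanner: for each candidate period p it
compares position i with i+p and reports maximal runs where adjacent
monomers agree at or above an identity floor over enough copies.  Arrays
that lie (≥50%) within called centromeres form the CTR catalog; candidate
progenitor LTR representatives are then aligned against each CTR array
separately (alignments never span two arrays), scored per 10-bp query bin
as S = L × N, and contiguous high-scoring bins become the intervals that
mark the satellite-homologous segment of the LTR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from . import pairwise
from .align import AlignmentHit, BinnedScoreTrack, bin_scores, encode, local_align
from .io import GenomeSequence, Interval, is_centromeric

_DECODE = np.array(list("ACGTN"))


@dataclass
class TandemRepeatArray:
    location: Interval
    period: int
    copy_number: float
    consensus: str
    mean_adjacent_identity: float
    sequence: str = ""

    def __len__(self) -> int:
        return len(self.location)


@dataclass
class CtrCatalog:
    arrays: list[TandemRepeatArray]
    total_bp: int
    fraction_of_centromere: float


@dataclass
class HighScoringInterval:
    query_id: str
    start: int               # bp on the query, aligned to the trace bin width
    end: int
    mean_score: float
    covered_ctr_bp: int
    sequence: str = ""


@dataclass
class TraceResult:
    tracks: dict[str, BinnedScoreTrack]
    intervals: list[HighScoringInterval]
    alignment_total_bp: int


def detect_tandem_repeats(seq: GenomeSequence | str,
                          min_period: int = 2,
                          max_period: int = 2000,
                          min_copies: int = 3,
                          min_identity: float = 0.8,
                          min_span: int = 20,
                          chrom_id: str = "seq",
                          offset: int = 0) -> list[TandemRepeatArray]:
    """Maximal tandem arrays by period-agreement scanning.

    For period p, positions i and i+p must agree at >= min_identity per
    monomer over a run spanning >= min_copies * p and >= min_span bp (the
    span floor keeps chance micro-runs of tiny periods out).  Overlapping
    calls at different periods are resolved to the larger array (ties to
    the smaller period).  *offset* shifts reported coordinates (useful when
    scanning a centromere slice of a chromosome).
    """
    if isinstance(seq, GenomeSequence):
        chrom_id = seq.chrom_id
        seq = seq.sequence
    if not (2 <= min_period <= max_period) or min_copies < 2:
        raise ValueError("need 2 <= min_period <= max_period, min_copies >= 2")
    codes = encode(seq)
    n = len(codes)
    candidates: list[TandemRepeatArray] = []
    for p in range(min_period, min(max_period, n // min_copies) + 1):
        agree = ((codes[p:] == codes[:-p]) & (codes[p:] < 4)).astype(np.float64)
        if len(agree) < p:
            break
        cs = np.concatenate([[0.0], np.cumsum(agree)])
        frac = (cs[p:] - cs[:len(agree) - p + 1]) / p  # per-monomer agreement
        marked = frac >= min_identity
        min_run = (min_copies - 2) * p + 1
        for rs, re in _runs(marked):
            if re - rs < min_run:
                continue
            span_end = re - 1 + 2 * p
            span = span_end - rs
            if span < max(min_copies * p, min_span):
                continue
            arr_seq = seq[rs:span_end]
            candidates.append(TandemRepeatArray(
                Interval(chrom_id, offset + rs, offset + span_end, "tr"),
                p, span / p, _consensus(codes[rs:span_end], p),
                float(frac[rs:re].mean()), arr_seq))
    # resolve overlaps: keep larger arrays, ties to smaller period; the
    # span is compared net of the 2p phasing pad so a harmonic (2p, 3p...)
    # of the true period cannot win on pad length alone
    candidates.sort(key=lambda a: (-(len(a) - 2 * a.period), a.period,
                                   a.location.start))
    kept: list[TandemRepeatArray] = []
    for cand in candidates:
        if any(cand.location.overlap(k.location) > 0 for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda a: a.location.start)
    return kept


def _runs(marked: np.ndarray) -> list[tuple[int, int]]:
    if not marked.any():
        return []
    d = np.diff(marked.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if marked[0]:
        starts.insert(0, 0)
    if marked[-1]:
        ends.append(len(marked))
    return list(zip(starts, ends))


def _consensus(codes: np.ndarray, p: int) -> str:
    n_full = len(codes) // p
    mat = codes[:n_full * p].reshape(n_full, p)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
    return "".join(_DECODE[np.argmax(counts, axis=0)])


def collect_ctrs(arrays: Sequence[TandemRepeatArray],
                 centromeres: Sequence[Interval]) -> CtrCatalog:
    """Centromeric arrays (≥50% overlap rule), their total bp and the
    fraction of the total centromere length they occupy."""
    kept = [a for a in arrays if is_centromeric(a.location, centromeres)]
    total_bp = sum(len(a) for a in kept)
    cen_total = sum(len(c) for c in centromeres)
    frac = total_bp / cen_total if cen_total else 0.0
    return CtrCatalog(list(kept), total_bp, frac)


def trace_origin(representatives: Mapping[str, str],
                 ctr_catalog: CtrCatalog,
                 bin_width: int = 10,
                 interval_score_threshold: float | None = None,
                 min_len: int = 30,
                 min_identity: float = 0.75) -> TraceResult:
    """Align each representative LTR to the CTR arrays and find the
    high-scoring query intervals.

    Each representative is aligned per array (never across array
    boundaries), its hits binned at *bin_width* on the query as S = L × N,
    and maximal runs of bins with S >= threshold become intervals.  The
    default threshold is adaptive per representative: mean + 2 sd of its
    non-zero bins.  ``alignment_total_bp`` counts unique CTR bases covered
    by any hit of any representative; each interval's ``covered_ctr_bp``
    counts CTR bases attributed to it (each base to at most one interval).
    """
    arrays = ctr_catalog.arrays
    tracks: dict[str, BinnedScoreTrack] = {}
    intervals: list[HighScoringInterval] = []
    covered_any = [np.zeros(len(a), dtype=bool) for a in arrays]
    attributed = [np.zeros(len(a), dtype=bool) for a in arrays]
    hits_by_rep: dict[str, list[tuple[AlignmentHit, int]]] = {}

    for rep_id in sorted(representatives):
        rep_seq = representatives[rep_id]
        rep_hits: list[tuple[AlignmentHit, int]] = []
        for ai, arr in enumerate(arrays):
            if not arr.sequence:
                raise ValueError("CTR array carries no sequence to align to")
            hits = local_align(rep_seq, arr.sequence, min_len=min_len,
                               min_identity=min_identity, query_id=rep_id)
            for h in hits:
                covered_any[ai][h.target_start:h.target_end] = True
                rep_hits.append((h, ai))
        hits_by_rep[rep_id] = rep_hits
        tracks[rep_id] = bin_scores(len(rep_seq), [h for h, _ in rep_hits],
                                    bin_width)

    alignment_total_bp = int(sum(c.sum() for c in covered_any))

    for rep_id in sorted(representatives):
        track = tracks[rep_id]
        S = track.S
        if not (S > 0).any():
            continue
        # adaptive cutoff over all bins: a homologous segment stands out as
        # a plateau far above the track mean; scattered weak alignment does
        # not clear its own mean + 2 sd
        thr = (interval_score_threshold if interval_score_threshold is not None
               else float(S.mean() + 2.0 * S.std()))
        marked = S >= max(thr, 1.0)
        rep_len = len(representatives[rep_id])
        for b0, b1 in _runs(marked):
            q0 = b0 * bin_width
            q1 = min(b1 * bin_width, rep_len)
            cov = 0
            for h, ai in hits_by_rep[rep_id]:
                t0, t1 = _lift_query_to_target(h, q0, q1)
                if t1 > t0:
                    seg = attributed[ai][t0:t1]
                    cov += int((~seg).sum())
                    seg[:] = True
            intervals.append(HighScoringInterval(
                rep_id, q0, q1, float(S[b0:b1].mean()), cov,
                representatives[rep_id][q0:q1]))
    intervals.sort(key=lambda iv: (-iv.mean_score, iv.query_id, iv.start))
    return TraceResult(tracks, intervals, alignment_total_bp)


def _lift_query_to_target(h: AlignmentHit, q0: int, q1: int) -> tuple[int, int]:
    """Target subrange of a hit for a query subrange (linear interpolation;
    exact for ungapped hits)."""
    a = max(q0, h.query_start)
    b = min(q1, h.query_end)
    if b <= a:
        return 0, 0
    qspan = h.query_end - h.query_start
    tspan = h.target_end - h.target_start
    scale = tspan / qspan
    if h.strand == "+":
        t0 = h.target_start + int(round((a - h.query_start) * scale))
        t1 = h.target_start + int(round((b - h.query_start) * scale))
    else:
        t0 = h.target_end - int(round((b - h.query_start) * scale))
        t1 = h.target_end - int(round((a - h.query_start) * scale))
    return max(t0, h.target_start), min(t1, h.target_end)


def coverage_stats(intervals: Sequence[HighScoringInterval],
                   alignment_total_bp: int) -> tuple[int, float]:
    """Total CTR bases under the high-scoring intervals and their percentage
    of all aligned CTR bases (2 decimals, half-up).  Undefined (NaN) when
    nothing aligned at all."""
    covered = int(sum(iv.covered_ctr_bp for iv in intervals))
    if alignment_total_bp == 0:
        return covered, math.nan
    if covered > alignment_total_bp:
        raise ValueError("covered bases exceed total aligned bases")
    pct = Decimal(100 * covered) / Decimal(alignment_total_bp)
    return covered, float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def interval_similarity(a: HighScoringInterval | str,
                        b: HighScoringInterval | str) -> float:
    """Sequence similarity between two high-scoring intervals.

    The shorter interval is fitted end-to-end into the longer (free end
    gaps on the longer only) and the identity over the fitted columns is
    returned — so unrelated intervals score near background rather than
    picking up a short perfect local match.
    """
    sa = a.sequence if isinstance(a, HighScoringInterval) else a
    sb = b.sequence if isinstance(b, HighScoringInterval) else b
    if not sa or not sb:
        raise ValueError("interval sequences must be non-empty")
    return pairwise.infix_identity(sa, sb).identity
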