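"""ChIP/Input enrichment, centromere interval calling, and boundary meta-profiles.

The functional centromere is delineated from the per-bin ratio of ChIP to
Input counts: bins at or above a threshold are marked, marked runs separated
by small gaps are merged, and short surviving intervals are dropped.  Ratios
are linear (not log2), with a pseudocount guarding zero-coverage bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import Interval, SignalTrack

logger = logging.getLogger("centrotrace")


@dataclass
class CentromereCall:
    """One called centromere interval with its mean ChIP/Input enrichment."""

    chrom_id: str
    interval: Interval
    mean_ratio: float
    n_bins: int
    is_primary: bool = False


@dataclass
class MetaProfile:
    """Mean signal in fixed bins around an element anchor (start or end)."""

    anchor: str          # "element_start" or "element_end"
    flank: int
    bin: int
    mean_signal: np.ndarray
    n_elements: int


def ratio_track(chip: SignalTrack, input_: SignalTrack,
                pseudocount: float = 1.0) -> SignalTrack:
    """Per-bin (ChIP + c) / (Input + c); all values finite and positive."""
    if chip.bin_width != input_.bin_width:
        raise ValueError("chip and input tracks have different bin widths")
    if chip.chrom_id != input_.chrom_id:
        raise ValueError("chip and input tracks are on different chromosomes")
    n = min(chip.n_bins, input_.n_bins)
    values = (chip.values[:n] + pseudocount) / (input_.values[:n] + pseudocount)
    return SignalTrack(chip.chrom_id, chip.bin_width, values)


def call_centromeres(ratio: SignalTrack, threshold: float = 2.0,
                     merge_gap: int = 50_000,
                     min_len: int = 100_000,
                     min_run: int = 3) -> list[CentromereCall]:
    """Threshold/merge/trim surrogate for manual centromere refinement.

    Bins with ratio >= threshold are marked; marked runs shorter than
    min_run bins are discarded as isolated noise spikes (a count-noise bin
    clears the threshold far more often than min_run adjacent ones); the
    surviving runs separated by gaps <= merge_gap (bp) are merged; merged
    intervals shorter than min_len are dropped; sub-threshold boundary bins
    are trimmed.  The call with the highest mean ratio per chromosome is
    flagged primary.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    bw = ratio.bin_width
    marked = ratio.values >= threshold
    if min_run > 1:
        padded = np.concatenate([[False], marked, [False]]).astype(np.int8)
        d = np.diff(padded)
        for rs, re in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
            if re - rs < min_run:
                marked[rs:re] = False
    if not marked.any():
        return []
    idx = np.nonzero(marked)[0]
    gap_bins = merge_gap // bw
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 <= gap_bins:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    calls: list[CentromereCall] = []
    for b0, b1 in runs:
        # trim boundary bins below threshold (no-op unless merged edges dip)
        while b0 <= b1 and ratio.values[b0] < threshold:
            b0 += 1
        while b1 >= b0 and ratio.values[b1] < threshold:
            b1 -= 1
        if b1 < b0:
            continue
        start, end = b0 * bw, (b1 + 1) * bw
        if end - start < min_len:
            continue
        mean = float(ratio.values[b0:b1 + 1].mean())
        calls.append(CentromereCall(
            ratio.chrom_id, Interval(ratio.chrom_id, start, end, "cen"),
            mean, b1 - b0 + 1))
    if calls:
        best = max(calls, key=lambda c: c.mean_ratio)
        best.is_primary = True
    return calls


def meta_profile(
    elements: Sequence[Interval],
    signal: SignalTrack | Mapping[str, SignalTrack],
    flank: int = 1000,
    bin: int = 100,
) -> tuple[MetaProfile, MetaProfile]:
    """Mean signal around element starts and ends, ±flank, strand-aware.

    Minus-strand elements are flipped: their "start" anchor is the interval
    end and the sampled bins run outward-to-inward in element orientation.
    Elements whose anchor lies closer than *flank* to a track edge are
    skipped (count logged).
    """
    if not elements:
        raise ValueError("need at least one element")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    tracks = ({signal.chrom_id: signal}
              if isinstance(signal, SignalTrack) else dict(signal))
    nbins = 2 * flank // bin
    sum_start = np.zeros(nbins)
    sum_end = np.zeros(nbins)
    n_used = 0
    n_skipped = 0
    for el in elements:
        track = tracks.get(el.chrom_id)
        if track is None:
            n_skipped += 1
            continue
        if el.strand == "-":
            anchors = (el.end, el.start)
        else:
            anchors = (el.start, el.end)
        rows = []
        ok = True
        for anchor in anchors:
            row = _sample(track, anchor - flank, anchor + flank, bin)
            if row is None:
                ok = False
                break
            rows.append(row)
        if not ok:
            n_skipped += 1
            continue
        if el.strand == "-":
            rows = [r[::-1] for r in rows]
        sum_start += rows[0]
        sum_end += rows[1]
        n_used += 1
    if n_skipped:
        logger.info("meta_profile: skipped %d/%d elements near track edges",
                    n_skipped, len(elements))
    if n_used == 0:
        raise ValueError("no element had full flanks inside the track")
    return (
        MetaProfile("element_start", flank, bin, sum_start / n_used, n_used),
        MetaProfile("element_end", flank, bin, sum_end / n_used, n_used),
    )


def _sample(track: SignalTrack, start: int, end: int,
            bin: int) -> np.ndarray | None:
    """Mean track value in consecutive *bin*-bp windows of [start, end)."""
    if start < 0 or end > track.n_bins * track.bin_width:
        return None
    edges = np.arange(start, end + 1, bin)
    out = np.empty(len(edges) - 1)
    for i in range(len(out)):
        b0 = edges[i] // track.bin_width
        b1 = (edges[i + 1] - 1) // track.bin_width
        out[i] = track.values[b0:b1 + 1].mean()
    return out
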