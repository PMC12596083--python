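"""Centromeric-retrotransposon discovery.

The workflow: census repeat families inside called centromeres, select
high-copy candidate families (resolving consensus containment), call the
intact LTR elements that align strongly to the candidate as centromeric
retrotransposons (CRs), pick the representative element by length, map its
genome-wide occupancy, and design/count a FISH probe window from its LTR.

A repeat copy, alignment hit, or probe match counts as centromeric when at
least 50% of its span lies inside a centromere — the single rule shared
with the enrichment index and the satellite catalog.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pairwise
from ._kernels import probe_scan
from .align import (AlignmentHit, BinnedScoreTrack, GenomeIndex, bin_scores,
                    encode, local_align, revcomp)
from .io import GenomeSequence, Interval, is_centromeric

logger = logging.getLogger("centrotrace")


@dataclass
class LtrElement:
    """An intact LTR retrotransposon: 5′LTR — internal domain — 3′LTR.

    Sub-intervals are stored in genomic coordinate order (``ltr5`` is the
    genomically left LTR); transcription orientation is applied at sequence
    extraction time from the strand.
    """

    element_id: str
    chrom_id: str
    span: Interval
    ltr5: Interval
    internal: Interval
    ltr3: Interval
    family_id: str
    subfamily: str | None = None
    insertion_time_mya: float | None = None

    def __post_init__(self) -> None:
        if not (self.ltr5.end <= self.internal.start
                and self.internal.end <= self.ltr3.start):
            raise ValueError(
                f"{self.element_id}: LTR/internal intervals out of order")
        for part in (self.ltr5, self.internal, self.ltr3):
            if part.start < self.span.start or part.end > self.span.end:
                raise ValueError(
                    f"{self.element_id}: part outside element span")

    @property
    def strand(self) -> str:
        return self.span.strand

    def length(self) -> int:
        return len(self.span)


@dataclass
class FamilyCensus:
    family_id: str
    centromeric_count: int
    genome_count: int
    consensus_len: int = 0


@dataclass
class ProbeSpec:
    """A fixed-length FISH probe window from a CR's LTR."""

    sequence: str
    length: int
    source_interval: Interval
    mismatch_frac: float = 0.03

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("probe length must equal sequence length")
        if not (0.0 <= self.mismatch_frac <= 0.1):
            raise ValueError("mismatch_frac must lie in [0, 0.1]")

    @property
    def max_mismatches(self) -> int:
        return math.floor(self.mismatch_frac * self.length)


@dataclass
class ProbeCount:
    copies: int
    cumulative_len: int


@dataclass
class OccupancyResult:
    cen_hits: int
    noncen_hits: int
    part_tracks: dict[str, BinnedScoreTrack]
    hits: list[AlignmentHit] = field(default_factory=list)


def _genome_map(genome: Sequence[GenomeSequence]) -> dict[str, str]:
    return {g.chrom_id: g.sequence for g in genome}


def element_sequence(element: LtrElement,
                     genome: Sequence[GenomeSequence] | Mapping[str, str]) -> str:
    """Full element sequence in transcription orientation."""
    seqs = genome if isinstance(genome, Mapping) else _genome_map(genome)
    s = seqs[element.chrom_id][element.span.start:element.span.end]
    return revcomp(s) if element.strand == "-" else s


# ---------------------------------------------------------------------------


def census_families(annotations: Sequence[tuple[Interval, str]],
                    centromeres: Sequence[Interval],
                    consensus_lens: Mapping[str, int] | None = None,
                    ) -> list[FamilyCensus]:
    """Exact per-family copy counts, genome-wide and centromeric (≥50% rule)."""
    genome_counts: dict[str, int] = {}
    cen_counts: dict[str, int] = {}
    for iv, family in annotations:
        genome_counts[family] = genome_counts.get(family, 0) + 1
        if is_centromeric(iv, centromeres):
            cen_counts[family] = cen_counts.get(family, 0) + 1
    out = [
        FamilyCensus(fam, cen_counts.get(fam, 0), genome_counts[fam],
                     0 if consensus_lens is None
                     else consensus_lens.get(fam, 0))
        for fam in sorted(genome_counts)
    ]
    out.sort(key=lambda c: (-c.centromeric_count, c.family_id))
    return out


def select_candidates(census: Sequence[FamilyCensus],
                      consensus_seqs: Mapping[str, str],
                      min_count: int = 100) -> list[str]:
    """High-copy centromeric families, with contained consensi dropped.

    Families above the copy floor are kept; if one kept family's consensus
    aligns over ≥90% of its own length at ≥90% identity within another kept
    family's consensus, the contained family is dropped and the container
    retained.
    """
    kept = [c for c in census if c.centromeric_count > min_count]
    for c in kept:
        if c.family_id not in consensus_seqs:
            raise KeyError(f"no consensus sequence for family {c.family_id!r}")
    kept_ids = [c.family_id for c in kept]
    dropped: set[str] = set()
    # longest containers first so a chain collapses to the maximal container
    by_len = sorted(kept_ids, key=lambda f: -len(consensus_seqs[f]))
    for small in reversed(by_len):
        for big in by_len:
            if big == small or big in dropped or small in dropped:
                continue
            if len(consensus_seqs[small]) > len(consensus_seqs[big]):
                continue
            res = pairwise.local_identity(consensus_seqs[small],
                                          consensus_seqs[big])
            span = res.a_span[1] - res.a_span[0]
            if (span / len(consensus_seqs[small]) >= 0.9
                    and res.identity >= 0.9):
                dropped.add(small)
                break
    return [f for f in kept_ids if f not in dropped]


def call_crs(candidate: str, elements: Sequence[LtrElement],
             genome: Sequence[GenomeSequence],
             min_cov: float = 0.5,
             min_identity: float = 0.8) -> tuple[list[str], str]:
    """Call CRs: elements whose alignment to the candidate covers enough.

    An element is a CR if local-alignment hits between the candidate and the
    element sequence cover >= min_cov of the shorter of the two at
    >= min_identity.  The representative is the CR whose length is closest
    to the candidate's (ties to the smaller element_id).
    """
    seqs = _genome_map(genome)
    cr_ids: list[str] = []
    lengths: dict[str, int] = {}
    for el in sorted(elements, key=lambda e: e.element_id):
        seq = element_sequence(el, seqs)
        hits = local_align(candidate, seq, min_len=50,
                           min_identity=min_identity, query_id="candidate")
        shorter = min(len(candidate), len(seq))
        covered = np.zeros(shorter, dtype=bool)
        for h in hits:
            if len(candidate) <= len(seq):
                covered[h.query_start:h.query_end] = True
            else:
                covered[h.target_start:h.target_end] = True
        if shorter and covered.sum() / shorter >= min_cov:
            cr_ids.append(el.element_id)
            lengths[el.element_id] = el.length()
    if not cr_ids:
        logger.info("call_crs: no element reached coverage %.2f", min_cov)
        return [], ""
    representative = min(
        cr_ids, key=lambda eid: (abs(lengths[eid] - len(candidate)), eid))
    return cr_ids, representative


def occupancy(element: LtrElement,
              genome: Sequence[GenomeSequence] | GenomeIndex,
              centromeres: Sequence[Interval],
              min_len: int = 100,
              min_identity: float = 0.8,
              bin_width: int = 100,
              genome_seqs: Sequence[GenomeSequence] | None = None,
              ) -> OccupancyResult:
    """Genome-wide copy counts of a CR, split centromeric / non-centromeric,
    plus separate binned score tracks for its LTRs and internal domain."""
    if isinstance(genome, GenomeIndex):
        index = genome
        if genome_seqs is None:
            raise ValueError("genome_seqs required when passing a GenomeIndex")
        seqs = _genome_map(genome_seqs)
    else:
        index = GenomeIndex(genome)
        seqs = _genome_map(genome)
    full = element_sequence(element, seqs)
    hits = local_align(full, index, min_len=min_len,
                       min_identity=min_identity,
                       query_id=element.element_id)
    # count whole-element occurrences: hits covering >= half the element
    cen = noncen = 0
    for h in hits:
        if h.aligned_cols < len(full) * 0.5:
            continue
        iv = Interval(h.target_chrom, h.target_start, h.target_end)
        if is_centromeric(iv, centromeres):
            cen += 1
        else:
            noncen += 1
    chrom_seq = seqs[element.chrom_id]
    parts = {}
    for name, iv in (("ltr5", element.ltr5), ("internal", element.internal),
                     ("ltr3", element.ltr3)):
        if len(iv) == 0:
            raise ValueError(f"{element.element_id}: empty part {name}")
        part_seq = chrom_seq[iv.start:iv.end]
        part_hits = local_align(part_seq, index, min_len=min_len,
                                min_identity=min_identity, query_id=name)
        parts[name] = bin_scores(len(part_seq), part_hits, bin_width)
    return OccupancyResult(cen, noncen, parts, hits)


# ---------------------------------------------------------------------------
# probe design and counting


def count_probe_copies(probe: ProbeSpec | str,
                       genome: Sequence[GenomeSequence],
                       mismatch_frac: float = 0.03,
                       ) -> dict[str, ProbeCount]:
    """Gapless full-length probe matches per chromosome, both strands.

    A copy is a placement with at most floor(mismatch_frac × length)
    mismatches; overlapping placements are collapsed to the best-scoring
    (fewest-mismatch, then leftmost) start.  cumulative_len is
    copies × probe length, mirroring a FISH-probe census table.
    """
    if isinstance(probe, ProbeSpec):
        seq = probe.sequence
        max_mm = probe.max_mismatches
    else:
        seq = probe
        max_mm = math.floor(mismatch_frac * len(seq))
    if not seq:
        raise ValueError("probe sequence must be non-empty")
    plen = len(seq)
    fwd = encode(seq)
    rev = encode(revcomp(seq))
    out: dict[str, ProbeCount] = {}
    for gs in genome:
        t = encode(gs.sequence)
        mm_f = probe_scan(t, fwd, max_mm)
        mm_r = probe_scan(t, rev, max_mm)
        if len(mm_f) == 0:
            out[gs.chrom_id] = ProbeCount(0, 0)
            continue
        mm = np.minimum(mm_f, mm_r)
        starts = np.nonzero(mm <= max_mm)[0]
        chosen = _collapse_overlaps(starts, mm[starts], plen)
        out[gs.chrom_id] = ProbeCount(len(chosen), len(chosen) * plen)
    return out


def _collapse_overlaps(starts: np.ndarray, mms: np.ndarray,
                       plen: int) -> list[int]:
    order = sorted(range(len(starts)), key=lambda i: (mms[i], starts[i]))
    accepted: list[int] = []
    for i in order:
        s = int(starts[i])
        if all(abs(s - a) >= plen for a in accepted):
            accepted.append(s)
    return sorted(accepted)


_ELEMENT_COLS = ["element_id", "chrom", "start", "end", "strand",
                 "ltr5_start", "ltr5_end", "internal_start", "internal_end",
                 "ltr3_start", "ltr3_end", "family_id", "subfamily",
                 "insertion_time_mya"]


def write_elements_tsv(elements: Sequence[LtrElement], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ELEMENT_COLS) + "\n")
        for el in elements:
            fh.write("\t".join(str(x) for x in (
                el.element_id, el.chrom_id, el.span.start, el.span.end,
                el.strand, el.ltr5.start, el.ltr5.end, el.internal.start,
                el.internal.end, el.ltr3.start, el.ltr3.end, el.family_id,
                el.subfamily or ".",
                "." if el.insertion_time_mya is None
                else f"{el.insertion_time_mya:g}")) + "\n")


def read_elements_tsv(path) -> list[LtrElement]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ELEMENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing element columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        strand = row.strand
        out.append(LtrElement(
            row.element_id, row.chrom,
            Interval(row.chrom, int(row.start), int(row.end),
                     row.element_id, strand),
            Interval(row.chrom, int(row.ltr5_start), int(row.ltr5_end),
                     strand=strand),
            Interval(row.chrom, int(row.internal_start),
                     int(row.internal_end), strand=strand),
            Interval(row.chrom, int(row.ltr3_start), int(row.ltr3_end),
                     strand=strand),
            row.family_id,
            None if row.subfamily == "." else row.subfamily,
            None if row.insertion_time_mya == "." else
            float(row.insertion_time_mya)))
    return out


def probe_report(counts: Mapping[str, ProbeCount],
                 probe_len: int) -> pd.DataFrame:
    """Per-chromosome probe census: copy number and cumulative length (bp)."""
    rows = [
        {"chrom": chrom, "copies": pc.copies,
         "cumulative_len": pc.copies * probe_len}
        for chrom, pc in counts.items()
    ]
    return pd.DataFrame(rows, columns=["chrom", "copies", "cumulative_len"])


def design_probe(cr: LtrElement,
                 genome: Sequence[GenomeSequence],
                 centromeres: Sequence[Interval],
                 probe_len: int = 376,
                 mismatch_frac: float = 0.03,
                 index: GenomeIndex | None = None) -> ProbeSpec:
    """Pick the probe window of the CR's LTRs with the best centromere focus.

    Every probe_len window of the 5′ and 3′ LTRs is scored as
    (centromeric copies − non-centromeric copies); the best window wins,
    ties resolved to the leftmost 5′-LTR window.  Copies are counted within
    LTR-homologous genomic regions found by one alignment pass, which makes
    the window scan cheap; the final census of the chosen window is the
    business of :func:`count_probe_copies`.
    """
    seqs = _genome_map(genome)
    if index is None:
        index = GenomeIndex(genome)
    max_mm = math.floor(mismatch_frac * probe_len)
    chrom_seq = seqs[cr.chrom_id]
    best: tuple[int, ProbeSpec] | None = None
    for ltr_iv in (cr.ltr5, cr.ltr3):
        ltr_seq = chrom_seq[ltr_iv.start:ltr_iv.end]
        if len(ltr_seq) < probe_len:
            if ltr_iv is cr.ltr5:
                raise ValueError(
                    f"LTR length {len(ltr_seq)} shorter than probe {probe_len}")
            continue
        hits = local_align(ltr_seq, index, min_len=max(20, probe_len // 2),
                           min_identity=0.7, query_id="ltr")
        # per-hit boolean match profile in query (LTR) coordinates
        profiles = []
        for h in hits:
            tseq = seqs[h.target_chrom][h.target_start:h.target_end]
            if h.strand == "-":
                tseq = revcomp(tseq)
            qs, qe = h.query_start, h.query_end
            if len(tseq) != qe - qs:
                continue  # gapped hit: skip in the design scan
            match = (encode(ltr_seq[qs:qe]) == encode(tseq)) & \
                    (encode(tseq) < 4)
            cen = is_centromeric(
                Interval(h.target_chrom, h.target_start, h.target_end),
                centromeres)
            prefix = np.concatenate([[0], np.cumsum(~match)])
            profiles.append((qs, qe, prefix, cen))
        n_windows = len(ltr_seq) - probe_len + 1
        for w in range(n_windows):
            score = 0
            for qs, qe, prefix, cen in profiles:
                if w < qs or w + probe_len > qe:
                    continue
                mm = int(prefix[w + probe_len - qs] - prefix[w - qs])
                if mm <= max_mm:
                    score += 1 if cen else -1
            if best is None or score > best[0]:
                src = Interval(cr.chrom_id, ltr_iv.start + w,
                               ltr_iv.start + w + probe_len, "probe",
                               cr.strand)
                best = (score, ProbeSpec(ltr_seq[w:w + probe_len], probe_len,
                                         src, mismatch_frac))
    assert best is not None
    return best[1]
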