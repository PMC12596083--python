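"""Centromeric retrotransposon enrichment index (CRI / CLTRI).

For one query element aligned genome-wide, each hit contributes the
identity-weighted aligned length L·I to either the centromeric or the
non-centromeric mass, by the shared ≥50%-overlap rule; the index is the
ratio of the two masses:

    CRI = Σ_CEN (L_i · I_i) / Σ_nonCEN (L_j · I_j)

A zero denominator with positive numerator is reported as an infinity flag
(no pseudocount), both masses zero as undefined.  The LTR-level variant
(CLTRI) applies the same formula to the hits of the element's LTR sequence
alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .align import AlignmentHit, GenomeIndex, local_align
from .discovery import LtrElement
from .io import GenomeSequence, Interval, is_centromeric


@dataclass
class EnrichmentResult:
    element_id: str
    cri: float                 # math.inf when noncen mass is zero; nan undefined
    cen_mass: float
    noncen_mass: float
    n_cen_hits: int
    n_noncen_hits: int

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.cri)

    @property
    def is_undefined(self) -> bool:
        return math.isnan(self.cri)


def compute_cri(hits: Sequence[AlignmentHit],
                centromeres: Sequence[Interval],
                element_id: str | None = None) -> EnrichmentResult:
    """Enrichment index from a hit table of one query element."""
    cen_mass = noncen_mass = 0.0
    n_cen = n_noncen = 0
    for h in hits:
        if not (0.0 <= h.I <= 1.0):
            raise ValueError(f"hit identity {h.I} outside [0, 1]")
        mass = h.L * h.I
        iv = Interval(h.target_chrom, h.target_start, h.target_end)
        if is_centromeric(iv, centromeres):
            cen_mass += mass
            n_cen += 1
        else:
            noncen_mass += mass
            n_noncen += 1
    if element_id is None:
        element_id = hits[0].query_id if hits else ""
    if noncen_mass > 0:
        cri = cen_mass / noncen_mass
    elif cen_mass > 0:
        cri = math.inf
    else:
        cri = math.nan
    return EnrichmentResult(element_id, cri, cen_mass, noncen_mass,
                            n_cen, n_noncen)


def compute_cltri(element: LtrElement,
                  genome: Sequence[GenomeSequence] | GenomeIndex,
                  centromeres: Sequence[Interval],
                  min_len: int = 100,
                  min_identity: float = 0.8,
                  genome_seqs: Sequence[GenomeSequence] | None = None,
                  ) -> EnrichmentResult:
    """CRI of the element's 5′ LTR sequence (3′ LTR if the 5′ is missing)."""
    if isinstance(genome, GenomeIndex):
        index = genome
        if genome_seqs is None:
            raise ValueError("genome_seqs required when passing a GenomeIndex")
        seqs = {g.chrom_id: g.sequence for g in genome_seqs}
    else:
        index = GenomeIndex(genome)
        seqs = {g.chrom_id: g.sequence for g in genome}
    chrom = seqs[element.chrom_id]
    for iv in (element.ltr5, element.ltr3):
        if iv is not None and len(iv) > 0:
            ltr_seq = chrom[iv.start:iv.end]
            break
    else:
        raise ValueError(f"{element.element_id}: no LTR interval available")
    hits = local_align(ltr_seq, index, min_len=min_len,
                       min_identity=min_identity,
                       query_id=element.element_id)
    return compute_cri(hits, centromeres, element_id=element.element_id)


def select_ncrs(results: Sequence[EnrichmentResult],
                threshold: float = 2.0) -> list[str]:
    """Centromere-specific elements: CRI >= threshold (infinity first),
    ranked descending, ties by element_id."""
    qualifying = [r for r in results
                  if r.is_infinite or (not r.is_undefined and r.cri >= threshold)]
    qualifying.sort(key=lambda r: (0 if r.is_infinite else 1,
                                   -r.cri if not r.is_infinite else 0.0,
                                   r.element_id))
    return [r.element_id for r in qualifying]
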