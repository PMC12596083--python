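"""Centromeric LTR extraction, insertion dating, and greedy identity clustering.

An LTR retrotransposon's two terminal repeats are identical at insertion
and diverge neutrally afterwards, so the element's age follows from their
pairwise divergence: with Jukes-Cantor correction
K = −(3/4)·ln(1 − 4p/3) of the proportion p of mismatched aligned columns
(gap columns excluded), the insertion time is T = K / (2μ) for a neutral
substitution rate μ (default 1.3e-8 substitutions/site/year, the
conventional plant LTR dating rate).

Clustering is greedy longest-first: each sequence joins the first existing
representative it matches at or above the identity threshold (local
alignment covering ≥80% of the shorter sequence), otherwise it founds a
new cluster — deterministic by explicit (length desc, id asc) ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import pairwise
from .align import revcomp
from .discovery import LtrElement
from .io import GenomeSequence


@dataclass
class DatingResult:
    element_id: str
    p_distance: float
    k_jc: float
    insertion_time_mya: float
    mu: float


@dataclass
class ClusterAssignment:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)


class SaturationError(ValueError):
    """LTR divergence beyond the Jukes-Cantor validity range (p >= 0.75)."""


def extract_cltrs(elements: Sequence[LtrElement],
                  genome: Sequence[GenomeSequence] | Mapping[str, str],
                  ) -> dict[str, tuple[str, str]]:
    """Per element: (5′ LTR, 3′ LTR) sequences in transcription orientation.

    For minus-strand elements the genomically right LTR is the 5′ one; both
    are reverse-complemented.
    """
    seqs = (genome if isinstance(genome, Mapping)
            else {g.chrom_id: g.sequence for g in genome})
    out: dict[str, tuple[str, str]] = {}
    for el in elements:
        chrom = seqs[el.chrom_id]
        for iv in (el.ltr5, el.ltr3):
            if iv.end > len(chrom):
                raise ValueError(
                    f"{el.element_id}: LTR interval beyond chromosome end")
        left = chrom[el.ltr5.start:el.ltr5.end]
        right = chrom[el.ltr3.start:el.ltr3.end]
        if el.strand == "-":
            out[el.element_id] = (revcomp(right), revcomp(left))
        else:
            out[el.element_id] = (left, right)
    return out


def date_insertion(ltr5: str, ltr3: str, mu: float = 1.3e-8,
                   element_id: str = "") -> DatingResult:
    """Insertion age from 5′/3′ LTR divergence under Jukes-Cantor."""
    if len(ltr5) < 100 or len(ltr3) < 100:
        raise ValueError("both LTRs must be at least 100 bp for dating")
    if mu <= 0:
        raise ValueError("mu must be positive")
    res = pairwise.global_identity(ltr5, ltr3)
    sub_cols = res.matches + res.mismatch_cols
    p = res.mismatch_cols / sub_cols if sub_cols else 0.0
    if p >= 0.75:
        raise SaturationError(
            f"p-distance {p:.3f} ≥ 0.75: divergence saturated, undatable")
    k = -0.75 * math.log1p(-4.0 * p / 3.0)
    time_mya = k / (2.0 * mu) / 1e6
    return DatingResult(element_id, p, k, time_mya, mu)


def date_elements(elements: Sequence[LtrElement],
                  genome: Sequence[GenomeSequence] | Mapping[str, str],
                  mu: float = 1.3e-8) -> list[DatingResult]:
    """Date every element; saturated pairs are skipped (flagged by absence)."""
    cltrs = extract_cltrs(elements, genome)
    out = []
    for el in elements:
        l5, l3 = cltrs[el.element_id]
        try:
            out.append(date_insertion(l5, l3, mu, element_id=el.element_id))
        except SaturationError:
            continue
    return out


def cluster_greedy(seqs: Mapping[str, str],
                   identity_threshold: float = 0.70,
                   min_coverage: float = 0.8) -> list[ClusterAssignment]:
    """Greedy longest-first clustering to representatives.

    Identity is matches / alignment columns of the best local alignment,
    required to cover >= min_coverage of the shorter sequence (otherwise
    the pair is treated as unrelated).
    """
    if not (0 < identity_threshold < 1):
        raise ValueError("identity_threshold must lie in (0, 1)")
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    clusters: list[ClusterAssignment] = []
    for sid in order:
        placed = False
        for cl in clusters:
            rep_seq = seqs[cl.representative_id]
            res = pairwise.local_identity(seqs[sid], rep_seq)
            if (res.coverage_shorter >= min_coverage
                    and res.identity >= identity_threshold):
                cl.member_ids.append(sid)
                cl.identities.append(res.identity)
                placed = True
                break
        if not placed:
            clusters.append(ClusterAssignment(sid, [sid], [1.0]))
    return clusters
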