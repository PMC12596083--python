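"""Single-pair alignment identities via Bio.Align.PairwiseAligner.

Used wherever the pipeline needs one identity number for one pair of
sequences (clustering, consensus containment, interval similarity, LTR
dating).  Scoring mirrors the genome-scale aligner: match +1, mismatch −1,
gap of length g costs 2 + g.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -3   # first gap base: open 2 + extend 1
    al.extend_gap_score = -1
    return al


_LOCAL = _make_aligner("local")
_GLOBAL = _make_aligner("global")


@dataclass
class PairwiseResult:
    identity: float        # matches / alignment columns (gap columns counted)
    columns: int
    matches: int
    mismatch_cols: int
    gap_cols: int
    coverage_shorter: float  # aligned span on the shorter sequence / its length
    a_span: tuple[int, int]
    b_span: tuple[int, int]


def _summarize(aln, len_a: int, len_b: int) -> PairwiseResult:
    counts = aln.counts()
    cols = counts.gaps + counts.identities + counts.mismatches
    blocks_a, blocks_b = aln.aligned
    a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b0, b1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
    shorter = min(len_a, len_b)
    span = (a1 - a0) if len_a <= len_b else (b1 - b0)
    return PairwiseResult(
        identity=counts.identities / cols if cols else 0.0,
        columns=cols,
        matches=counts.identities,
        mismatch_cols=counts.mismatches,
        gap_cols=counts.gaps,
        coverage_shorter=span / shorter if shorter else 0.0,
        a_span=(a0, a1),
        b_span=(b0, b1),
    )


def local_identity(a: str, b: str) -> PairwiseResult:
    """Best local alignment of two sequences, summarized."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = next(iter(_LOCAL.align(a.upper(), b.upper())))
    return _summarize(aln, len(a), len(b))


def global_identity(a: str, b: str) -> PairwiseResult:
    """Global (end-to-end) alignment of two sequences, summarized."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = next(iter(_GLOBAL.align(a.upper(), b.upper())))
    return _summarize(aln, len(a), len(b))


def infix_identity(a: str, b: str) -> PairwiseResult:
    """Fit the shorter sequence end-to-end into the longer one.

    End gaps on the longer sequence are free; every base of the shorter
    sequence must be accounted for.  Unlike a best-local-alignment
    identity — which is ~1.0 even for unrelated sequences, via some short
    perfect match — this drops to background (~0.5) when the pair shares
    no homologous stretch.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    al = _make_aligner("global")
    # free end gaps on the target (the longer sequence): in Bio.Align terms
    # a gap in the target is an "insertion"
    al.open_left_insertion_score = 0
    al.extend_left_insertion_score = 0
    al.open_right_insertion_score = 0
    al.extend_right_insertion_score = 0
    aln = next(iter(al.align(long_.upper(), short.upper())))
    blocks_t, blocks_q = aln.aligned
    matches = mismatch = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        for x, y in zip(long_[ts:te].upper(), short[qs:qe].upper()):
            if x == y and x in "ACGT":
                matches += 1
            else:
                mismatch += 1
    gap_cols = 0
    for i in range(1, len(blocks_t)):
        gap_cols += int(blocks_t[i][0] - blocks_t[i - 1][1])
        gap_cols += int(blocks_q[i][0] - blocks_q[i - 1][1])
    # unaligned overhang of the shorter sequence counts as gap columns
    gap_cols += int(blocks_q[0][0]) + int(len(short) - blocks_q[-1][1])
    cols = matches + mismatch + gap_cols
    long_span = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    short_span = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    a_span, b_span = ((short_span, long_span) if len(a) <= len(b)
                      else (long_span, short_span))
    return PairwiseResult(
        identity=matches / cols if cols else 0.0,
        columns=cols, matches=matches, mismatch_cols=mismatch,
        gap_cols=gap_cols,
        coverage_shorter=(short_span[1] - short_span[0]) / len(short),
        a_span=a_span, b_span=b_span)
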