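# Methods

## Centromere delineation from ChIP enrichment

The pipeline's entry point is a pair of per-bin read-count tracks (default
1-kb bins): CENH3 ChIP and Input.  Enrichment is the linear ratio
`(ChIP_b + c) / (Input_b + c)` with pseudocount `c = 1` per bin, which
keeps deserts finite without biasing enriched bins.  Intervals are called
by marking bins at or above a threshold (default 2.0), discarding marked
runs shorter than `min_run` bins (default 3) as isolated count-noise
spikes — a single Poisson bin clears a 2-fold threshold roughly 1% of the
time at λ = 30, three adjacent bins essentially never — then merging runs
separated by ≤ 50 kb, dropping intervals shorter than 100 kb, and trimming
sub-threshold boundary bins.  The highest-mean interval per chromosome is
flagged primary.  These rules replace a manual genome-browser refinement
step with a reproducible, configurable surrogate; on block-shaped truth
with ≥5-fold enrichment they recover boundaries to within one bin.

Meta-profiles average the signal in fixed windows (±1 kb, 100-bp steps)
around element starts and ends, flipping minus-strand elements so the
profile is in element orientation; elements whose flanks leave the track
are skipped and counted.

## Local alignment and the binned score S = L × N

Genome-scale alignment is seed-and-extend: exact 13-mer seeds from a
sorted k-mer index, clustered by diagonal (break at diagonal jumps > 32 or
target jumps > max(500, query length)), each cluster resolved by a banded
affine-gap Smith–Waterman (match +1, mismatch −1, gap of length g costs
2 + g; numba kernel).  Within a window, hits are extracted best-first with
target masking, so reported hits never overlap on the target; extraction
stops below the minimal qualifying score `(2·min_identity − 1)·min_len`.
Lowercase bases align as uppercase; N never matches.  Two same-strand hits
overlapping ≥90% on the target are merged keeping the higher score, and a
reverse-palindromic query reports its self-identical alignment once.

Numerical/scope choices: the DP band covers the cluster's diagonal range
±16, so a single hit may drift at most 16 bp through indels; DP rows are
restricted to the cluster's query range ± max(4·min_len, 120), so an
alignment extending further past its last exact 13-mer seed than that
allowance would be clipped.  Both limits are generous for the package's
use cases (planted-copy recovery, satellite tracing) and are verified
against an exhaustive quadratic Smith–Waterman oracle in the test suite.

`bin_scores` partitions the query into fixed bins (100 bp for occupancy
maps, 10 bp for the origin trace) and scores each as S = L × N: L is the
number of bin positions covered by the union of hit query intervals
(bounded by the bin width) and N the count of hits intersecting the bin.
S therefore rises with both coverage and repetitiveness, which is what
makes LTR-derived satellite amplification stand out.

Single-pair identities (dating, clustering, containment, interval
similarity) use Bio.Align.PairwiseAligner with the same scoring.

## Enrichment index

CRI = Σ_CEN(L·I) / Σ_nonCEN(L·I) over an element's genome-wide hits; a hit
is centromeric when ≥50% of its target interval lies inside a centromere —
the same majority rule used by the family census, probe classification and
the CTR catalog, so all modules agree on what "centromeric" means.  A zero
denominator with positive numerator is reported as a flagged infinity (no
pseudocount; the ranking places infinities first), both masses zero as
undefined.  CLTRI applies the formula to hits of the 5′ LTR alone (3′ if
the 5′ is missing).  The default centromere-specificity cutoff is 2.0;
in simulation it separates a planted centromere-biased family (CRI ≫ 2)
from uniformly placed families (CRI ≈ cen/non-cen genome fraction ≈ 0.25)
with a wide margin.

## Probe design and census

The probe is the fixed-length window (default 376 bp) of the CR
representative's LTRs maximizing centromeric minus non-centromeric copy
count, ties to the leftmost 5′-LTR window.  A copy is a gapless
full-length match on either strand with at most ⌊0.03 × 376⌋ = 11
mismatches; overlapping placements collapse to the fewest-mismatch, then
leftmost start.  Cumulative length is exactly copies × probe length,
matching a copies-times-unit census.  During the window scan, copies are
counted inside LTR-homologous regions found by one alignment pass (exact
for gapless hits); the final census of the chosen window is a full
genome scan.

## LTR dating and clustering

The two LTRs of an element are identical at insertion.  Dating aligns them
globally, takes p = mismatched columns / substitution columns (gap columns
excluded), corrects K = −(3/4)·ln(1 − 4p/3) (Jukes–Cantor; p ≥ 0.75 raises
a saturation error), and reports T = K / (2μ) with
μ = 1.3 × 10⁻⁸ substitutions/site/year — the conventional plant LTR
dating rate, configurable.

Clustering is greedy longest-first: sequences ordered by (length desc, id
asc); each joins the first representative with local-alignment identity ≥
the threshold (default 0.70) over ≥80% of the shorter sequence, else
founds a cluster.  The explicit ordering makes cluster membership and
representatives deterministic.  The coverage floor keeps short spurious
local matches from merging unrelated LTRs; conversely, pairs near the
threshold that share no exact 13-mer would be separated by a seeded
aligner, which is why clustering identity uses the exhaustive pairwise
aligner instead.

## Tandem repeats and origin tracing

The TR detector is a period-agreement scanner: for each period p it
compares position i with i + p, smooths agreement per monomer, and reports
maximal runs with per-monomer agreement ≥ 0.8 spanning ≥ 3 copies and
≥ 20 bp (the span floor keeps chance dinucleotide micro-runs out of the
call set).  Consensus is the per-column majority over phased copies.
Overlapping calls at different periods are resolved by span net of the
2p phasing pad, then smaller period — otherwise a harmonic (2p, 3p, …) of
the true period would win purely on its longer pad.  It is a detector for
planted-array recovery and cataloging, not a reimplementation of any
external TR program's scoring.

Arrays lying ≥50% inside centromeres form the CTR catalog (total bp and
fraction of centromere length).  The origin trace aligns each clustered
LTR representative against each CTR array separately — alignments never
span array boundaries, so concatenation cannot fabricate chimeric hits —
bins the hits at 10 bp on the representative, and marks maximal runs of
bins with S ≥ mean(S) + 2·sd(S) (computed over all bins of that
representative; an explicit threshold can be supplied) as high-scoring
intervals.  Each interval reports the unique CTR bases under its hits
(each CTR base attributed to at most one interval), and
`coverage_stats` reports their total as a percentage of all aligned CTR
bases, rounded half-up to two decimals.  Interval-to-interval similarity
fits the shorter interval end-to-end into the longer (free end gaps on the
longer only), so unrelated intervals score near the ~50% random-DNA
background instead of picking up a short perfect local match.

## Synthetic data

The generator emulates the study design end to end.  Defaults: 3
chromosomes of 3 Mb, one 600-kb centromere each starting at 45% of the
chromosome; 5 LTR families of 6-kb elements (800-bp LTRs); the CR family
planted with 30 centromeric + 3 non-centromeric full copies and 20
centromeric solo LTRs; 40 uniformly placed copies per background family;
one tandem array per centromere of 50 × 100-bp monomers (2% substitutions
per copy) amplified from a segment of the oldest family's LTR (or from a
random monomer as a negative control); ChIP/Input as per-bin Poisson
counts with λ = 30 and folds 5 (centromere) and 7.5 (CR LTRs inside
centromeres).

Family ages default to 0.35 Mya for the CR family — young, so its copies
are near-identical and a fixed-mismatch probe stays high-copy — and 2.46
Mya for the satellite-donating background family, mirroring a young
centromere-biased clade alongside an older satellite-seeding one; the
others are 0.8/1.2/1.6.  Ages are injected by mutating each LTR
independently with the Jukes–Cantor event probability
p = (3/4)(1 − e^(−4k/3)) for k = μT per branch, so the dating estimator is
unbiased by construction.  Planted-copy divergence is substitutions-only;
indel support in `mutate_sequence` exists for stress tests but the
planted truth stays coordinate-exact, which also makes hit lift-over in
the trace exact.  Background sequence is i.i.d. uniform ACGT — no GC
structure, no nested/fragmented insertions, no segmental duplication — so
passing recovery tests demonstrates correctness of the estimators under
the modeled noise, not performance on real genomes.

All randomness derives from the config seed (separate streams for genome
generation and track simulation); a given (config, seed) reproduces
byte-identical outputs.

## Problem sizes and thresholds used in validation

The recovery suites and the acceptance script run the generator at its
defaults (9 Mb per genome, 20 seeds where replication is called for) and
make two scale-appropriate analysis choices: the family-census copy floor
is 20 (the full-size default of 100 reflects fragment-level annotation
counts on real genomes, far above the ~50 planted centromeric CR copies),
and TR detection scans periods 10–300 (the planted monomer is 100 bp; the
library default scans up to 2000).  Insertion-age recovery uses a
two-family configuration (0.35 vs 2.46 Mya) and requires non-overlapping
mean ± 3 sd; boundary recovery requires ≤ 1 bin; the origin trace requires
≥ 80% positional overlap with the true source segment.

## Known limitations

- The seeded aligner needs one exact 13-mer per hit; sensitivity decays
  for pairs more than ~15% diverged.  Absolute alignment scores depend on
  the scoring scheme and are not comparable across aligners — only the
  S = L × N construction and its profile shape are.
- The TR detector reports periods up to rotation of the consensus and
  resolves harmonics heuristically; it does not decompose higher-order
  repeat structure.
- Dating assumes equal rates across sites and no gene conversion between
  LTRs; conversion would bias ages young in real data.
- `call_centromeres` reports bin-aligned coordinates; sub-bin boundary
  precision is out of reach by construction.
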