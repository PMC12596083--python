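"""Synthetic genomes with planted centromeres, LTR families, and satellites.

The generator emulates the statistical structure the pipeline assumes: each
chromosome carries one centromere; LTR-retrotransposon families are planted
as full 5′LTR—internal—3′LTR elements whose two LTRs are identical at
insertion and then diverge according to the family age; one family (the CR
family, made the oldest by default) is planted with a strong centromere
bias plus solo-LTR copies; each centromere receives one tandem array
amplified from a segment of the oldest family's LTR; and ChIP/Input tracks
are Poisson bin counts with configurable fold enrichment over centromeres
and CR LTRs.

Ages are injected with the Jukes-Cantor per-site event probability
p = 3/4·(1 − exp(−4k/3)) for k = μ·T expected substitutions per site per
branch, so the downstream JC69 dating estimator is unbiased by
construction.  All randomness derives from the config seed; a given
(config, seed) reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import encode, revcomp
from .discovery import LtrElement, write_elements_tsv
from .io import (GenomeSequence, Interval, SignalTrack, write_bed, write_fasta,
                 write_repeat_annotations_gff3, write_signal)

_BASES = np.array(list("ACGT"))

MUTATION_RATE = 1.3e-8  # substitutions / site / year


def jc_event_prob(k: float) -> float:
    """Probability a site differs from the ancestor after k expected
    substitutions/site under Jukes-Cantor."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic genome."""

    n_chroms: int = 3
    chrom_len: int = 3_000_000
    cen_len: int = 600_000
    cen_position: float = 0.45      # fraction of chromosome where cen starts
    n_families: int = 5
    planted_cr_copies_cen: int = 30     # genome-wide, split across centromeres
    planted_cr_copies_noncen: int = 3
    background_copies: int = 40         # per non-CR family, uniform placement
    element_len: int = 6000
    ltr_len: int = 800
    extra_ltr_solo_copies_cen: int = 20
    tr_source: str = "cltr_segment"     # or "random"
    tr_segment_len: int = 100
    tr_copy_number: int = 50
    tr_copy_mut: float = 0.02           # per-copy substitution probability
    ages_mya: tuple[float, ...] | None = None
    chip_fold_cen: float = 5.0
    chip_fold_cr_ltr: float = 7.5
    input_lambda: float = 30.0
    bin_width: int = 1000
    mu: float = MUTATION_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cen_len >= self.chrom_len:
            raise ValueError("cen_len must be smaller than chrom_len")
        if self.chip_fold_cen < 1 or self.chip_fold_cr_ltr < 1:
            raise ValueError("ChIP folds must be >= 1")
        if self.tr_source not in ("cltr_segment", "random"):
            raise ValueError("tr_source must be 'cltr_segment' or 'random'")

    def family_ages(self) -> list[float]:
        """Per-family ages in Mya.

        By default the CR family (index 0) is young — its copies are
        near-identical, so a fixed-mismatch probe stays high-copy — while
        one background family is old and donates the tandem-array source
        segment, mirroring a young centromere-biased clade alongside an
        older satellite-seeding one.
        """
        if self.ages_mya is not None:
            ages = list(self.ages_mya)
        else:
            ages = [0.35, 2.46, 0.8, 1.2, 1.6]
        while len(ages) < self.n_families:
            ages.append(ages[-1])
        return ages[:self.n_families]

    @property
    def cr_family(self) -> str:
        return "rf1"

    def family_ids(self) -> list[str]:
        return [f"rf{i + 1}" for i in range(self.n_families)]


@dataclass
class TrArrayTruth:
    location: Interval
    source_family: str
    source_start: int    # segment coordinates on the ancestral LTR
    source_end: int
    period: int
    copy_number: int


@dataclass
class SyntheticTruth:
    centromeres: list[Interval]
    elements: list[LtrElement]
    solo_ltrs: list[Interval]
    tr_arrays: list[TrArrayTruth]
    chip_fold: dict[str, np.ndarray]
    family_ages: dict[str, float]
    cr_family: str
    consensi: dict[str, str]          # ancestral full element per family
    ancestral_ltrs: dict[str, str]


@dataclass
class SimResult:
    genome: list[GenomeSequence]
    truth: SyntheticTruth
    annotations: list[tuple[Interval, str]]
    config: SimConfig


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def mutate_sequence(seq: str, sub_prob: float, indel_prob: float = 0.0,
                    seed: int | np.random.Generator = 0) -> str:
    """Mutate a sequence: per-site substitution to a uniformly chosen
    different base with *sub_prob*, per-site 1-bp indel with *indel_prob*.

    Deterministic given the seed (or an explicit Generator).  N bases are
    left untouched by substitutions.
    """
    if not (0 <= sub_prob < 0.5) or not (0 <= indel_prob < 0.5):
        raise ValueError("probabilities must lie in [0, 0.5)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    codes = encode(seq).copy()
    n = len(codes)
    if sub_prob > 0:
        hit = (rng.random(n) < sub_prob) & (codes < 4)
        shift = rng.integers(1, 4, n)
        codes[hit] = (codes[hit] + shift[hit]) % 4
    out = "".join(np.append(_BASES, "N")[codes])
    if indel_prob > 0:
        hit = np.nonzero(rng.random(n) < indel_prob)[0]
        is_ins = rng.random(len(hit)) < 0.5
        ins_base = _BASES[rng.integers(0, 4, len(hit))]
        pieces = []
        prev = 0
        for pos, ins, base in zip(hit, is_ins, ins_base):
            if ins:
                pieces.append(out[prev:pos])
                pieces.append(base)
                prev = pos
            else:
                pieces.append(out[prev:pos])
                prev = pos + 1
        pieces.append(out[prev:])
        out = "".join(pieces)
    return out


def _place(rng: np.random.Generator, lo: int, hi: int, length: int,
           occupied: list[tuple[int, int]], max_tries: int = 2000) -> int:
    """A start position in [lo, hi - length] not overlapping occupied spans."""
    if hi - lo < length:
        raise ValueError("planted features exceed available space")
    for _ in range(max_tries):
        s = int(rng.integers(lo, hi - length + 1))
        e = s + length
        if all(e <= a or s >= b for a, b in occupied):
            occupied.append((s, e))
            return s
    raise ValueError("planted features exceed available space (packing failed)")


def generate_genome(config: SimConfig) -> SimResult:
    """Generate the genome, its truth tables, and repeat annotations."""
    rng = np.random.default_rng([config.seed, 11])
    fams = config.family_ids()
    ages = dict(zip(fams, config.family_ages()))
    internal_len = config.element_len - 2 * config.ltr_len
    if internal_len <= 0:
        raise ValueError("element_len must exceed twice ltr_len")

    anc_ltr = {f: random_dna(rng, config.ltr_len) for f in fams}
    anc_int = {f: random_dna(rng, internal_len) for f in fams}
    consensi = {f: anc_ltr[f] + anc_int[f] + anc_ltr[f] for f in fams}

    oldest = max(fams, key=lambda f: (ages[f], f))
    if config.tr_source == "cltr_segment":
        src_start = int(rng.integers(0, config.ltr_len - config.tr_segment_len + 1))
        monomer = anc_ltr[oldest][src_start:src_start + config.tr_segment_len]
        tr_source = (oldest, src_start, src_start + config.tr_segment_len)
    else:
        monomer = random_dna(rng, config.tr_segment_len)
        tr_source = ("random", 0, config.tr_segment_len)

    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chroms)]
    centromeres = []
    cen_bounds: dict[str, tuple[int, int]] = {}
    chrom_codes: dict[str, np.ndarray] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for cid in chrom_ids:
        chrom_codes[cid] = rng.integers(0, 4, config.chrom_len,
                                        dtype=np.uint8)
        cs = int(config.chrom_len * config.cen_position)
        ce = cs + config.cen_len
        centromeres.append(Interval(cid, cs, ce, "cen"))
        cen_bounds[cid] = (cs, ce)
        occupied[cid] = []

    elements: list[LtrElement] = []
    solo_ltrs: list[Interval] = []
    annotations: list[tuple[Interval, str]] = []
    tr_truth: list[TrArrayTruth] = []

    def overwrite(cid: str, start: int, seq: str) -> None:
        chrom_codes[cid][start:start + len(seq)] = encode(seq)

    def plant_element(cid: str, fam: str, lo: int, hi: int, idx: int) -> None:
        age = ages[fam]
        p = jc_event_prob(config.mu * age * 1e6)
        l5 = mutate_sequence(anc_ltr[fam], p, seed=rng)
        l3 = mutate_sequence(anc_ltr[fam], p, seed=rng)
        ints = mutate_sequence(anc_int[fam], p, seed=rng)
        elem = l5 + ints + l3
        strand = "+" if rng.random() < 0.5 else "-"
        s = _place(rng, lo, hi, len(elem), occupied[cid])
        overwrite(cid, s, elem if strand == "+" else revcomp(elem))
        eid = f"{fam}_e{idx:04d}"
        span = Interval(cid, s, s + len(elem), eid, strand)
        L = config.ltr_len
        elements.append(LtrElement(
            eid, cid, span,
            Interval(cid, s, s + L, strand=strand),
            Interval(cid, s + L, s + L + internal_len, strand=strand),
            Interval(cid, s + L + internal_len, s + len(elem), strand=strand),
            fam, insertion_time_mya=age))
        annotations.append((span, fam))

    # tandem arrays first (one per centromere)
    for cid in chrom_ids:
        cs, ce = cen_bounds[cid]
        copies = [mutate_sequence(monomer, config.tr_copy_mut, seed=rng)
                  for _ in range(config.tr_copy_number)]
        arr = "".join(copies)
        s = _place(rng, cs, ce, len(arr), occupied[cid])
        overwrite(cid, s, arr)
        tr_truth.append(TrArrayTruth(
            Interval(cid, s, s + len(arr), "tr_array"),
            tr_source[0], tr_source[1], tr_source[2],
            config.tr_segment_len, config.tr_copy_number))

    # CR family: centromere-biased full copies + solo LTRs + few outside
    cr = config.cr_family
    counter = 0
    for i in range(config.planted_cr_copies_cen):
        cid = chrom_ids[i % len(chrom_ids)]
        cs, ce = cen_bounds[cid]
        plant_element(cid, cr, cs, ce, counter)
        counter += 1
    for i in range(config.planted_cr_copies_noncen):
        cid = chrom_ids[i % len(chrom_ids)]
        cs, ce = cen_bounds[cid]
        lo, hi = (0, cs) if rng.random() < 0.5 else (ce, config.chrom_len)
        plant_element(cid, cr, lo, hi, counter)
        counter += 1
    p_cr = jc_event_prob(config.mu * ages[cr] * 1e6)
    for i in range(config.extra_ltr_solo_copies_cen):
        cid = chrom_ids[i % len(chrom_ids)]
        cs, ce = cen_bounds[cid]
        seq = mutate_sequence(anc_ltr[cr], p_cr, seed=rng)
        strand = "+" if rng.random() < 0.5 else "-"
        s = _place(rng, cs, ce, len(seq), occupied[cid])
        overwrite(cid, s, seq if strand == "+" else revcomp(seq))
        iv = Interval(cid, s, s + len(seq), f"{cr}_solo{i:03d}", strand)
        solo_ltrs.append(iv)
        annotations.append((iv, cr))

    # background families: uniform genome-wide placement
    for fam in fams:
        if fam == cr:
            continue
        for i in range(config.background_copies):
            cid = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            plant_element(cid, fam, 0, config.chrom_len, counter)
            counter += 1

    genome = [GenomeSequence(cid, "".join(_BASES[chrom_codes[cid]]))
              for cid in chrom_ids]

    # expected per-bin ChIP fold
    bw = config.bin_width
    nbins = math.ceil(config.chrom_len / bw)
    fold: dict[str, np.ndarray] = {
        cid: np.ones(nbins, dtype=float) for cid in chrom_ids}
    for cid in chrom_ids:
        cs, ce = cen_bounds[cid]
        fold[cid][cs // bw:(ce - 1) // bw + 1] = config.chip_fold_cen
    cr_ltr_spans = (
        [(el.chrom_id, el.ltr5.start, el.ltr5.end) for el in elements
         if el.family_id == cr]
        + [(el.chrom_id, el.ltr3.start, el.ltr3.end) for el in elements
           if el.family_id == cr]
        + [(iv.chrom_id, iv.start, iv.end) for iv in solo_ltrs])
    for cid, s, e in cr_ltr_spans:
        cs, ce = cen_bounds[cid]
        if s >= cs and e <= ce:
            fold[cid][s // bw:(e - 1) // bw + 1] = config.chip_fold_cr_ltr

    truth = SyntheticTruth(centromeres, elements, solo_ltrs, tr_truth, fold,
                           ages, cr, consensi, dict(anc_ltr))
    return SimResult(genome, truth, annotations, config)


def simulate_chip(sim: SimResult,
                  config: SimConfig | None = None,
                  ) -> dict[str, tuple[SignalTrack, SignalTrack]]:
    """Poisson ChIP and Input bin counts from the truth's fold profile."""
    config = config or sim.config
    rng = np.random.default_rng([config.seed, 23])
    out = {}
    for gs in sim.genome:
        fold = sim.truth.chip_fold[gs.chrom_id]
        inp = rng.poisson(config.input_lambda, len(fold)).astype(float)
        chip = rng.poisson(config.input_lambda * fold).astype(float)
        out[gs.chrom_id] = (
            SignalTrack(gs.chrom_id, config.bin_width, chip),
            SignalTrack(gs.chrom_id, config.bin_width, inp))
    return out


def write_outputs(sim: SimResult, outdir: str | Path,
                  tracks: dict[str, tuple[SignalTrack, SignalTrack]] | None = None,
                  ) -> None:
    """Write genome.fa, truth tables, annotations and ChIP tracks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome, outdir / "genome.fa")
    write_bed(sim.truth.centromeres, outdir / "centromeres.bed")
    write_elements_tsv(sim.truth.elements, outdir / "elements.tsv")
    write_repeat_annotations_gff3(sim.annotations, outdir / "repeats.gff3")
    with open(outdir / "tr_arrays.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tsource_family\tsource_start\t"
                 "source_end\tperiod\tcopies\n")
        for t in sim.truth.tr_arrays:
            fh.write(f"{t.location.chrom_id}\t{t.location.start}\t"
                     f"{t.location.end}\t{t.source_family}\t{t.source_start}\t"
                     f"{t.source_end}\t{t.period}\t{t.copy_number}\n")
    if tracks is None:
        tracks = simulate_chip(sim)
    lengths = {g.chrom_id: g.length for g in sim.genome}
    write_signal([c for c, _ in tracks.values()], outdir / "chip.bg", lengths)
    write_signal([i for _, i in tracks.values()], outdir / "input.bg", lengths)
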