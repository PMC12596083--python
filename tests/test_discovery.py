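import numpy as np
import pytest

from centrotrace import (GenomeSequence, Interval, LtrElement, ProbeSpec,
                         call_crs, census_families, count_probe_copies,
                         design_probe, element_sequence, occupancy,
                         probe_report, read_elements_tsv, select_candidates,
                         write_elements_tsv)
from centrotrace.align import revcomp
from centrotrace.io import is_centromeric

from conftest import random_dna
from _oracles import oracle_probe_count


def _element(eid, chrom, start, total, ltr, strand="+", family="fam"):
    return LtrElement(
        eid, chrom, Interval(chrom, start, start + total, eid, strand),
        Interval(chrom, start, start + ltr, strand=strand),
        Interval(chrom, start + ltr, start + total - ltr, strand=strand),
        Interval(chrom, start + total - ltr, start + total, strand=strand),
        family)


class TestCensus:
    CEN = [Interval("c1", 1000, 2000)]

    def test_full_containment_and_majority_rule(self):
        annots = [(Interval("c1", 1100, 1200), "A"),
                  (Interval("c1", 940, 1040), "B")]   # 40% inside
        census = census_families(annots, self.CEN)
        by_fam = {c.family_id: c for c in census}
        assert (by_fam["A"].centromeric_count, by_fam["A"].genome_count) == (1, 1)
        assert (by_fam["B"].centromeric_count, by_fam["B"].genome_count) == (0, 1)
        # 60% inside counts
        census = census_families([(Interval("c1", 960, 1060), "C")], self.CEN)
        assert census[0].centromeric_count == 1

    def test_counts_match_bruteforce_on_synthetic_truth(self, small_sim):
        census = census_families(small_sim.annotations,
                                 small_sim.truth.centromeres)
        for c in census:
            ivs = [iv for iv, fam in small_sim.annotations
                   if fam == c.family_id]
            brute_cen = sum(
                1 for iv in ivs
                if is_centromeric(iv, small_sim.truth.centromeres))
            assert (c.centromeric_count, c.genome_count) == (brute_cen,
                                                             len(ivs))


class TestSelectCandidates:
    def _census(self, counts):
        from centrotrace import FamilyCensus
        return [FamilyCensus(f, n, n) for f, n in counts.items()]

    def test_threshold(self, rng):
        seqs = {"A": random_dna(rng, 500), "B": random_dna(rng, 500)}
        out = select_candidates(self._census({"A": 150, "B": 99}), seqs,
                                min_count=100)
        assert out == ["A"]

    def test_contained_consensus_dropped(self, rng):
        big = random_dna(rng, 800)
        seqs = {"A": big, "B": big[200:500]}
        out = select_candidates(self._census({"A": 150, "B": 160}), seqs,
                                min_count=100)
        assert out == ["A"]

    def test_containment_chain_keeps_maximal(self, rng):
        big = random_dna(rng, 900)
        seqs = {"A": big, "B": big[100:700], "C": big[200:500]}
        out = select_candidates(self._census({"A": 150, "B": 150, "C": 150}),
                                seqs, min_count=100)
        assert out == ["A"]

    def test_missing_consensus_raises(self):
        with pytest.raises(KeyError, match="A"):
            select_candidates(self._census({"A": 150}), {}, min_count=100)


class TestCallCrs:
    def test_identical_element_is_cr_and_representative(self, rng):
        cand = random_dna(rng, 3000)
        genome = [GenomeSequence("c1", random_dna(rng, 500) + cand
                                 + random_dna(rng, 500))]
        el = _element("e1", "c1", 500, 3000, 400)
        crs, rep = call_crs(cand, [el], genome)
        assert crs == ["e1"] and rep == "e1"

    def test_small_shared_segment_not_cr(self, rng):
        cand = random_dna(rng, 3000)
        seq = cand[:150] + random_dna(rng, 2850)  # 5% shared
        genome = [GenomeSequence("c1", seq)]
        el = _element("e1", "c1", 0, 3000, 400)
        crs, rep = call_crs(cand, [el], genome, min_cov=0.5)
        assert crs == [] and rep == ""

    def test_representative_closest_length(self, rng):
        """Candidate 12281 bp; CR lengths 11454/9000/13900 -> 11454 wins."""
        cand = random_dna(rng, 12_281)
        pieces = {"e_11454": cand[:11_454],
                  "e_09000": cand[:9_000],
                  "e_13900": cand + random_dna(rng, 13_900 - 12_281)}
        genome, elements = [], []
        for eid, seq in pieces.items():
            genome.append(GenomeSequence(eid + "_chr", seq))
            elements.append(_element(eid, eid + "_chr", 0, len(seq), 500))
        crs, rep = call_crs(cand, elements, genome)
        assert set(crs) == set(pieces)
        assert rep == "e_11454"


class TestOccupancy:
    def test_planted_copy_counts_and_ltr_excess(self, small_sim):
        truth = small_sim.truth
        cr_els = [e for e in truth.elements if e.family_id == truth.cr_family]
        rep = cr_els[0]
        res = occupancy(rep, small_sim.genome, truth.centromeres,
                        min_len=100, min_identity=0.8)
        cfg = small_sim.config
        assert res.cen_hits == cfg.planted_cr_copies_cen
        assert res.noncen_hits == cfg.planted_cr_copies_noncen
        # solo LTR copies make the LTR tracks outscore the internal domain
        # (compared per bin: the parts have different lengths)
        ltr_mean = (res.part_tracks["ltr5"].S.mean()
                    + res.part_tracks["ltr3"].S.mean()) / 2
        assert ltr_mean > res.part_tracks["internal"].S.mean()

    def test_unique_element_counts_itself(self, rng):
        genome = [GenomeSequence("c1", random_dna(rng, 6000))]
        el = _element("solo", "c1", 1000, 3000, 400)
        res = occupancy(el, genome, [Interval("c1", 0, 100)],
                        min_len=100, min_identity=0.8)
        assert (res.cen_hits, res.noncen_hits) == (0, 1)


class TestProbe:
    def test_exact_matching_equals_naive_scan(self, rng):
        probe = random_dna(rng, 40)
        target = (random_dna(rng, 300) + probe + random_dna(rng, 200)
                  + revcomp(probe) + random_dna(rng, 300))
        counts = count_probe_copies(probe, [GenomeSequence("c1", target)],
                                    mismatch_frac=0.0)
        assert counts["c1"].copies == oracle_probe_count(probe, target, 0) == 2

    def test_mismatch_cap_and_collapse(self, rng):
        probe = random_dna(rng, 100)
        mutated = list(probe)
        for p in (10, 40, 70):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        target = random_dna(rng, 200) + "".join(mutated) + random_dna(rng, 200)
        gs = [GenomeSequence("c1", target)]
        assert count_probe_copies(probe, gs, mismatch_frac=0.03).get(
            "c1").copies == 1   # 3 mismatches <= floor(0.03*100)=3
        assert count_probe_copies(probe, gs, mismatch_frac=0.02).get(
            "c1").copies == 0
        assert count_probe_copies(probe, gs, mismatch_frac=0.03)[
            "c1"].cumulative_len == 100

    def test_zero_copies(self, rng):
        probe = random_dna(rng, 50)
        counts = count_probe_copies(probe, [GenomeSequence("c1", "A" * 2000)],
                                    mismatch_frac=0.03)
        assert (counts["c1"].copies, counts["c1"].cumulative_len) == (0, 0)

    def test_probe_report_cumulative_column(self):
        from centrotrace.discovery import ProbeCount
        df = probe_report({"c1": ProbeCount(5, 5 * 376)}, 376)
        assert df.loc[0, "cumulative_len"] == 1880

    def test_design_single_window_and_validation(self, rng):
        genome_seq = random_dna(rng, 3000)
        genome = [GenomeSequence("c1", genome_seq)]
        el = _element("e1", "c1", 200, 1152, 376)  # LTR exactly probe-sized
        probe = design_probe(el, genome, [Interval("c1", 0, 1500)],
                             probe_len=376)
        assert probe.sequence == genome_seq[200:576]
        assert (probe.source_interval.start, probe.source_interval.end) == (
            200, 576)
        short = _element("e2", "c1", 200, 900, 250)
        with pytest.raises(ValueError, match="shorter than probe"):
            design_probe(short, genome, [], probe_len=376)

    def test_design_prefers_centromere_amplified_window(self, rng):
        """One LTR window planted 6x in the centromere, another 3x outside:
        the centromere-focused window wins the (cen - noncen) score."""
        ltr = random_dna(rng, 800)
        internal = random_dna(rng, 1400)
        elem = ltr + internal + ltr
        good = ltr[200:576]       # to be amplified inside the centromere
        bad = ltr[400:776]        # amplified outside
        parts = [random_dna(rng, 500), elem, random_dna(rng, 500)]
        for _ in range(6):
            parts += [good, random_dna(rng, 120)]
        cen_end = sum(len(p) for p in parts) + 300
        parts += [random_dna(rng, 300)]
        for _ in range(3):
            parts += [bad, random_dna(rng, 120)]
        parts += [random_dna(rng, 400)]
        genome = [GenomeSequence("c1", "".join(parts))]
        cen = [Interval("c1", 0, cen_end)]
        el = _element("e1", "c1", 500, len(elem), 800)
        probe = design_probe(el, genome, cen, probe_len=376)
        assert probe.sequence == good
        assert (probe.source_interval.start, probe.source_interval.end) == (
            700, 1076)
        counts = count_probe_copies(probe, genome)
        assert counts["c1"].copies >= 7   # six planted copies + both LTR spans


class TestElementTsv:
    def test_roundtrip(self, tmp_path, small_sim):
        path = tmp_path / "els.tsv"
        write_elements_tsv(small_sim.truth.elements, path)
        back = read_elements_tsv(path)
        orig = small_sim.truth.elements
        assert len(back) == len(orig)
        assert all(a.element_id == b.element_id and a.span == b.span
                   and a.ltr5 == b.ltr5 and a.family_id == b.family_id
                   for a, b in zip(back, orig))
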