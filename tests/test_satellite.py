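import math

import numpy as np
import pytest

from centrotrace import (Interval, collect_ctrs, coverage_stats,
                         detect_tandem_repeats, interval_similarity,
                         mutate_sequence, trace_origin)
from centrotrace.satellite import CtrCatalog, HighScoringInterval, TandemRepeatArray

from conftest import random_dna


def _rotations(s):
    return {s[i:] + s[:i] for i in range(len(s))}


class TestDetect:
    def test_perfect_array_recovered(self, rng):
        seq = random_dna(rng, 400) + "ACGT" * 50 + random_dna(rng, 400)
        arrays = detect_tandem_repeats(seq, min_period=2, max_period=50,
                                       min_copies=3, min_identity=0.9)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 4
        assert a.copy_number == pytest.approx(50, abs=1)
        assert a.consensus in _rotations("ACGT")
        # flanks are random: the array must sit inside the planted region
        assert a.location.start >= 395 and a.location.end <= 605

    def test_random_sequence_yields_nothing(self):
        for seed in range(5):
            seq = random_dna(np.random.default_rng(seed), 10_000)
            assert detect_tandem_repeats(seq, min_period=10, max_period=200,
                                         min_copies=3, min_identity=0.8) == []

    def test_mutated_monomer_array_recovered(self):
        srng = np.random.default_rng(4)
        monomer = random_dna(srng, 100)
        arr = "".join(mutate_sequence(monomer, 0.05, seed=srng)
                      for _ in range(30))
        seq = random_dna(srng, 500) + arr + random_dna(srng, 500)
        arrays = detect_tandem_repeats(seq, min_period=10, max_period=300,
                                       min_copies=3, min_identity=0.8)
        assert len(arrays) == 1
        a = arrays[0]
        assert abs(a.period - 100) <= 2
        assert a.copy_number == pytest.approx(30, abs=1)


class TestCollect:
    def _array(self, chrom, start, end):
        return TandemRepeatArray(Interval(chrom, start, end), 10,
                                 (end - start) / 10, "A" * 10, 0.95, "")

    def test_fraction_arithmetic(self):
        cen = [Interval("c1", 0, 1_000_000)]
        cat = collect_ctrs([self._array("c1", 100_000, 110_000)], cen)
        assert cat.total_bp == 10_000
        assert cat.fraction_of_centromere == pytest.approx(0.01)

    def test_outside_arrays_excluded(self):
        cen = [Interval("c1", 0, 1000)]
        cat = collect_ctrs([self._array("c1", 5000, 6000)], cen)
        assert cat.arrays == [] and cat.total_bp == 0

    def test_mixed_set_matches_bruteforce(self, rng):
        cen = [Interval("c1", 1000, 3000), Interval("c2", 0, 2000)]
        arrays = [self._array("c1", s, s + 400)
                  for s in (500, 900, 1500, 2800, 4000)]
        arrays += [self._array("c2", 1900, 2300)]
        cat = collect_ctrs(arrays, cen)
        expected = [a for a in arrays
                    if sum(max(0, min(a.location.end, c.end)
                               - max(a.location.start, c.start))
                           for c in cen if c.chrom_id == a.location.chrom_id)
                    >= 0.5 * len(a)]
        assert cat.arrays == expected
        assert cat.total_bp == sum(len(a) for a in expected)


class TestTrace:
    def test_unrelated_representative_empty_track(self, rng):
        rep = random_dna(rng, 600)
        arr_seq = "TTAGGC" * 200
        cat = CtrCatalog([TandemRepeatArray(
            Interval("c1", 0, len(arr_seq)), 6, 200.0, "TTAGGC", 1.0,
            arr_seq)], len(arr_seq), 0.01)
        res = trace_origin({"rep": rep}, cat)
        assert res.tracks["rep"].S.sum() == 0
        assert res.intervals == [] and res.alignment_total_bp == 0

    def test_amplified_segment_found_others_flat(self):
        """A CTR array amplified from one representative's 100-bp segment:
        that representative carries the high-scoring interval, an unrelated
        one stays flat — and a sharing representative reports a consistent
        query position."""
        srng = np.random.default_rng(11)
        rep_a = random_dna(srng, 700)
        rep_b = random_dna(srng, 700)
        shared = rep_a[300:400]
        rep_c = random_dna(srng, 300) + shared + random_dna(srng, 300)
        arr = "".join(mutate_sequence(shared, 0.02, seed=srng)
                      for _ in range(40))
        cat = CtrCatalog([TandemRepeatArray(
            Interval("c1", 0, len(arr)), 100, 40.0, shared, 0.97, arr)],
            len(arr), 0.01)
        res = trace_origin({"A": rep_a, "B": rep_b, "C": rep_c},
                           cat, bin_width=10)
        assert res.tracks["B"].S.sum() == 0
        a_ivs = [iv for iv in res.intervals if iv.query_id == "A"]
        c_ivs = [iv for iv in res.intervals if iv.query_id == "C"]
        assert len(a_ivs) == 1 and len(c_ivs) == 1
        # interval on A overlaps the true source segment [300, 400)
        ov = max(0, min(a_ivs[0].end, 400) - max(a_ivs[0].start, 300))
        assert ov / 100 >= 0.8
        # C's interval sits over its own copy of the shared segment
        ov_c = max(0, min(c_ivs[0].end, 400) - max(c_ivs[0].start, 300))
        assert ov_c / 100 >= 0.8
        assert interval_similarity(a_ivs[0], c_ivs[0]) >= 0.95


class TestCoverageStats:
    def _iv(self, covered):
        return HighScoringInterval("q", 0, 100, 10.0, covered)

    def test_saturation_and_empty(self):
        assert coverage_stats([self._iv(500)], 500) == (500, 100.00)
        assert coverage_stats([], 500) == (0, 0.00)

    def test_undefined_when_nothing_aligned(self):
        covered, pct = coverage_stats([], 0)
        assert covered == 0 and math.isnan(pct)

    def test_rounding_half_up_two_decimals(self):
        # 1/8 of 1000 = 12.5 % exactly: half-up gives 12.50; and a
        # repeating fraction rounds at the printed precision
        assert coverage_stats([self._iv(125)], 1000)[1] == 12.50
        assert coverage_stats([self._iv(1)], 3)[1] == 33.33


class TestIntervalSimilarity:
    def test_identity_and_planted_mismatches(self, rng):
        seq = random_dna(rng, 100)
        assert interval_similarity(seq, seq) == 1.0
        mutated = list(seq)
        for p in range(0, 100, 10):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        sim = interval_similarity(seq, "".join(mutated))
        assert sim == pytest.approx(0.90, abs=0.03)

    def test_unrelated_sequences_dissimilar(self):
        for seed in range(5):
            srng = np.random.default_rng(seed)
            a, b = random_dna(srng, 100), random_dna(srng, 100)
            assert interval_similarity(a, b) < 0.6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            interval_similarity("", "ACGT")
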