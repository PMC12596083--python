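import math

import numpy as np
import pytest

from centrotrace import (GenomeSequence, Interval, LtrElement,
                         SaturationError, cluster_greedy, date_insertion,
                         extract_cltrs, mutate_sequence)
from centrotrace.align import revcomp

from conftest import random_dna


def _element(chrom, start, ltr, internal, strand):
    total = 2 * ltr + internal
    return LtrElement(
        "e1", chrom, Interval(chrom, start, start + total, "e1", strand),
        Interval(chrom, start, start + ltr, strand=strand),
        Interval(chrom, start + ltr, start + ltr + internal, strand=strand),
        Interval(chrom, start + total - ltr, start + total, strand=strand),
        "fam")


class TestExtractCltrs:
    def test_plus_strand_verbatim(self, rng):
        l5, l3 = random_dna(rng, 300), random_dna(rng, 300)
        seq = random_dna(rng, 100) + l5 + random_dna(rng, 500) + l3 \
            + random_dna(rng, 100)
        el = _element("c1", 100, 300, 500, "+")
        out = extract_cltrs([el], [GenomeSequence("c1", seq)])
        assert out["e1"] == (l5, l3)

    def test_minus_strand_swapped_and_reversed(self, rng):
        # a minus-strand element: its transcription-5' LTR is the
        # genomically right one, reverse-complemented
        l5, l3 = random_dna(rng, 300), random_dna(rng, 300)
        seq = random_dna(rng, 100) + revcomp(l3) + random_dna(rng, 500) \
            + revcomp(l5) + random_dna(rng, 100)
        el = _element("c1", 100, 300, 500, "-")
        out = extract_cltrs([el], [GenomeSequence("c1", seq)])
        assert out["e1"] == (l5, l3)

    def test_out_of_bounds_rejected(self, rng):
        el = _element("c1", 100, 300, 500, "+")
        with pytest.raises(ValueError, match="beyond"):
            extract_cltrs([el], [GenomeSequence("c1", "ACGT" * 100)])


class TestDating:
    def test_identical_ltrs_age_zero(self, rng):
        ltr = random_dna(rng, 500)
        r = date_insertion(ltr, ltr)
        assert r.p_distance == 0 and r.k_jc == 0
        assert r.insertion_time_mya == 0

    def test_one_percent_divergence_hand_computed(self, rng):
        """p = 0.01 under JC69: K = -(3/4)ln(1 - 0.04/3) = 0.0100672...,
        T = K / (2 * 1.3e-8) = 0.38720 Mya."""
        ltr = random_dna(rng, 1000)
        positions = rng.choice(1000, size=10, replace=False)
        other = list(ltr)
        for p in positions:
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        r = date_insertion(ltr, "".join(other), mu=1.3e-8)
        assert r.p_distance == pytest.approx(0.01)
        assert r.k_jc == pytest.approx(0.0100672, abs=1e-6)
        assert r.insertion_time_mya == pytest.approx(0.38720, abs=1e-4)

    def test_symmetric_and_monotone(self, rng):
        a = random_dna(rng, 600)
        b = mutate_sequence(a, 0.05, seed=1)
        c = mutate_sequence(a, 0.15, seed=2)
        assert date_insertion(a, b).k_jc == date_insertion(b, a).k_jc
        assert date_insertion(a, c).insertion_time_mya > \
            date_insertion(a, b).insertion_time_mya

    def test_simulated_pairs_recover_truth(self, rng):
        """LTR pairs mutated independently at per-site prob 0.02 date to
        ~2x0.02 substitutions/site within 15% averaged over 20 seeds."""
        times = []
        for seed in range(20):
            srng = np.random.default_rng(seed)
            anc = random_dna(srng, 800)
            l5 = mutate_sequence(anc, 0.02, seed=srng)
            l3 = mutate_sequence(anc, 0.02, seed=srng)
            times.append(date_insertion(l5, l3).k_jc)
        # 0.02 event prob per branch corresponds to k ~= -3/4 ln(1-4*.02/3)
        k_branch = -0.75 * math.log1p(-4 * 0.02 / 3)
        assert np.mean(times) == pytest.approx(2 * k_branch, rel=0.15)

    def test_saturation_flagged(self):
        a = "A" * 200
        b = "C" * 200
        with pytest.raises(SaturationError):
            date_insertion(a, b)

    def test_short_ltrs_rejected(self, rng):
        with pytest.raises(ValueError, match="100 bp"):
            date_insertion(random_dna(rng, 50), random_dna(rng, 500))


class TestClusterGreedy:
    def test_identical_sequences_collapse(self, rng):
        seq = random_dna(rng, 300)
        clusters = cluster_greedy({f"s{i}": seq for i in range(5)}, 0.70)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "s0"
        assert sorted(clusters[0].member_ids) == [f"s{i}" for i in range(5)]
        assert all(i >= 0.70 for i in clusters[0].identities)

    def test_two_separated_groups(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        seqs = {"a1": a, "a2": mutate_sequence(a, 0.05, seed=1),
                "b1": b, "b2": mutate_sequence(b, 0.05, seed=2)}
        clusters = cluster_greedy(seqs, 0.70)
        groups = [set(c.member_ids) for c in clusters]
        assert {"a1", "a2"} in groups and {"b1", "b2"} in groups

    def test_generative_truth_membership(self):
        """20 mutated copies of 2 ancestors (10% within, ~50% between)
        cluster with perfect membership."""
        srng = np.random.default_rng(99)
        anc = [random_dna(srng, 500), random_dna(srng, 500)]
        seqs = {}
        for i in range(20):
            src = i % 2
            seqs[f"g{src}_{i:02d}"] = mutate_sequence(
                anc[src], 0.10, seed=srng)
        clusters = cluster_greedy(seqs, 0.70)
        assert len(clusters) == 2
        for cl in clusters:
            prefixes = {m.split("_")[0] for m in cl.member_ids}
            assert len(prefixes) == 1
            assert len(cl.member_ids) == 10
            assert all(i >= 0.70 for i in cl.identities)

    def test_cluster_count_nonincreasing_in_threshold(self, rng):
        anc = random_dna(rng, 400)
        seqs = {f"s{i}": mutate_sequence(anc, 0.02 * i, seed=i)
                for i in range(8)}
        counts = [len(cluster_greedy(seqs, thr))
                  for thr in (0.95, 0.85, 0.75)]
        assert counts == sorted(counts, reverse=True)
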