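import numpy as np
import pandas as pd
import pytest

from txgc.hic import filter_self_ligation, overlap_pairs, permutation_test

from helpers import brute_force_overlap


def _contacts(rows):
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])


def _pairs(rows):
    return pd.DataFrame(rows, columns=["probe_i", "probe_j", "chrom_i", "pos_i", "chrom_j", "pos_j"])


class TestSelfLigation:
    def test_close_intrachromosomal_removed(self):
        c = _contacts([("chr1", 1000, 2000, "chr1", 11_000, 12_000)])  # midpoints 10 kb apart
        assert len(filter_self_ligation(c)) == 0

    def test_exactly_20kb_retained(self):
        c = _contacts([("chr1", 1000, 2000, "chr1", 21_000, 22_000)])  # exactly 20 kb
        assert len(filter_self_ligation(c)) == 1

    def test_interchromosomal_untouched(self):
        c = _contacts([("chr1", 1000, 2000, "chr2", 1500, 2500)])
        assert len(filter_self_ligation(c)) == 1


class TestOverlapPairs:
    def test_interchromosomal_overlap_at_500kb(self):
        pairs = _pairs([("A", "B", "chr1", 1_000_000, "chr2", 2_000_000)])
        contacts = _contacts([("chr1", 1_200_000, 1_201_000, "chr2", 1_900_000, 1_901_000)])
        res = overlap_pairs(pairs, contacts, window=500_000)
        assert res.n_overlapping == 1
        assert res.overlapping_pairs == [("A", "B")]

    def test_same_geometry_fails_at_100kb(self):
        pairs = _pairs([("A", "B", "chr1", 1_000_000, "chr2", 2_000_000)])
        contacts = _contacts([("chr1", 1_200_000, 1_201_000, "chr2", 1_900_000, 1_901_000)])
        # chr1 distance to anchor edge is 199 000 > 100 000
        assert overlap_pairs(pairs, contacts, window=100_000).n_overlapping == 0

    def test_swapped_anchor_assignment_counts(self):
        pairs = _pairs([("A", "B", "chr2", 1_950_000, "chr1", 1_150_000)])
        contacts = _contacts([("chr1", 1_200_000, 1_201_000, "chr2", 1_900_000, 1_901_000)])
        assert overlap_pairs(pairs, contacts, window=100_000).n_overlapping == 1

    def test_close_intrachromosomal_pair_excluded(self):
        pairs = _pairs([("A", "B", "chr1", 1_000_000, "chr1", 1_300_000)])
        contacts = _contacts([("chr1", 900_000, 1_100_000, "chr1", 1_250_000, 1_400_000)])
        res = overlap_pairs(pairs, contacts, window=500_000)
        assert res.n_pairs_evaluated == 0
        assert res.n_overlapping == 0

    def test_matches_brute_force(self, rng):
        chroms = ["chr1", "chr2", "chr3"]
        pairs = _pairs(
            [
                (f"P{k}", f"Q{k}", rng.choice(chroms), int(rng.integers(1, 5_000_000)),
                 rng.choice(chroms), int(rng.integers(1, 5_000_000)))
                for k in range(40)
            ]
        )
        starts = rng.integers(1, 5_000_000, size=30)
        contacts = _contacts(
            [
                (rng.choice(chroms), int(s), int(s + 10_000),
                 rng.choice(chroms), int(t), int(t + 10_000))
                for s, t in zip(starts, rng.integers(1, 5_000_000, size=30))
            ]
        )
        for window in (100_000, 500_000):
            res = overlap_pairs(pairs, contacts, window)
            n_eval, n_overlap = brute_force_overlap(pairs, contacts, window)
            assert res.n_pairs_evaluated == n_eval
            assert res.n_overlapping == n_overlap

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            overlap_pairs(_pairs([("A", "B", "chr1", 1, "chr2", 2)]), _contacts([]), 0)


class TestPermutationTest:
    def test_planted_enrichment_reaches_minimum_p(self, rng):
        # contacts exactly at many observed pair loci, none matching shuffles
        pairs = []
        contacts = []
        for k in range(12):
            ci, cj = f"chr{k % 3 + 1}", f"chr{(k + 1) % 3 + 1}"
            pi = int(1_000_000 + k * 50_000_000)
            pj = int(2_000_000 + k * 50_000_000)
            pairs.append((f"P{k}", f"Q{k}", ci, pi, cj, pj))
            contacts.append((ci, pi - 500, pi + 500, cj, pj - 500, pj + 500))
        B = 1000
        res = permutation_test(_pairs(pairs), _contacts(contacts), window=1000, B=B, seed=5)
        assert res.observed == 12
        assert res.p_two_tailed == pytest.approx(2.0 / (B + 1))

    def test_observed_equals_identity_permutation(self):
        pairs = _pairs(
            [
                ("A", "B", "chr1", 1_000_000, "chr2", 2_000_000),
                ("C", "D", "chr2", 9_000_000, "chr1", 7_000_000),
                ("E", "F", "chr1", 30_000_000, "chr1", 90_000_000),
            ]
        )
        contacts = _contacts([("chr1", 990_000, 1_010_000, "chr2", 1_990_000, 2_010_000)])
        res = overlap_pairs(pairs, contacts, window=100_000)
        perm = permutation_test(pairs, contacts, window=100_000, B=50, seed=1)
        assert perm.observed == res.n_overlapping

    def test_p_bounded_by_add_one_rule(self):
        pairs = _pairs(
            [
                ("A", "B", "chr1", 1_000_000, "chr2", 2_000_000),
                ("C", "D", "chr2", 9_000_000, "chr1", 7_000_000),
            ]
        )
        contacts = _contacts([("chr3", 1, 100, "chr3", 200_000, 200_100)])
        B = 99
        res = permutation_test(pairs, contacts, window=10_000, B=B, seed=2)
        assert 2.0 / (B + 1) <= res.p_two_tailed <= 1.0

    def test_false_positive_rate_calibrated(self):
        # contacts unrelated to any pair locus: reject rarely
        rejections = 0
        n_draws = 50
        for draw in range(n_draws):
            rng = np.random.default_rng(100 + draw)
            pairs = _pairs(
                [
                    (f"P{k}", f"Q{k}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 40_000_000)),
                     f"chr{rng.integers(1, 4)}", int(rng.integers(1, 40_000_000)))
                    for k in range(15)
                ]
            )
            starts1 = rng.integers(50_000_000, 90_000_000, size=20)
            starts2 = rng.integers(50_000_000, 90_000_000, size=20)
            contacts = _contacts(
                [
                    (f"chr{rng.integers(1, 4)}", int(s1), int(s1 + 5000),
                     f"chr{rng.integers(1, 4)}", int(s2), int(s2 + 5000))
                    for s1, s2 in zip(starts1, starts2)
                ]
            )
            res = permutation_test(pairs, contacts, window=500_000, B=199, seed=draw)
            if res.p_two_tailed < 0.05:
                rejections += 1
        assert rejections <= 10  # ~alpha * n_draws plus generous slack

    def test_zero_permutations_rejected(self):
        pairs = _pairs([("A", "B", "chr1", 1, "chr2", 2), ("C", "D", "chr1", 5, "chr2", 6)])
        with pytest.raises(ValueError):
            permutation_test(pairs, _contacts([]), window=100, B=0)
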