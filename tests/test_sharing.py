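"""Sharing counts, run lengths, and the pSGS/SGS statistics vs brute force."""

from itertools import combinations

import numpy as np
import pytest

from psgs.genotypes import HET, HOM1, HOM2, MISSING
from psgs.sharing import (
    locus_sharing_counts,
    pair_shares,
    pairwise_run_lengths,
    psgs_statistic,
    region_sharing_summary,
    run_lengths,
    run_lengths_genome,
    sgs_statistic,
    threshold_run_lengths,
    two_pedigree_statistic,
)

# ---------------------------------------------------------------- oracles --


def oracle_pair_shares(a: int, b: int) -> bool:
    a = HET if a == MISSING else a
    b = HET if b == MISSING else b
    return {a, b} != {HOM1, HOM2}


def oracle_run_lengths(ind) -> list:
    """Quadratic scan: expand every interval of consecutive True."""
    L = len(ind)
    out = [0] * L
    for i in range(L):
        if not ind[i]:
            continue
        lo = i
        while lo > 0 and ind[lo - 1]:
            lo -= 1
        hi = i
        while hi < L - 1 and ind[hi + 1]:
            hi += 1
        out[i] = hi - lo + 1
    return out


def oracle_pairwise(codes, boundaries):
    N, L = codes.shape
    out = []
    for j, k in combinations(range(N), 2):
        row = np.empty(L, dtype=int)
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            ind = [oracle_pair_shares(codes[j, i], codes[k, i]) for i in range(a, b)]
            row[a:b] = oracle_run_lengths(ind)
        out.append(row)
    return np.array(out)


def oracle_sgs(codes, boundaries):
    N, L = codes.shape
    row = np.empty(L, dtype=int)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        ind = [
            all(
                oracle_pair_shares(codes[j, i], codes[k, i])
                for j, k in combinations(range(N), 2)
            )
            for i in range(a, b)
        ]
        row[a:b] = oracle_run_lengths(ind)
    return row


def random_codes(rng, N, L, p_missing=0.05):
    codes = rng.choice(
        [HOM1, HET, HOM2], size=(N, L), p=[0.3, 0.4, 0.3]
    ).astype(np.int8)
    codes[rng.random((N, L)) < p_missing] = MISSING
    return codes


# ------------------------------------------------------------------ tests --


class TestPairShares:
    def test_opposite_homozygotes_never_share(self):
        assert not pair_shares(HOM1, HOM2)
        assert not pair_shares(HOM2, HOM1)

    def test_missing_treated_as_heterozygote(self):
        assert pair_shares(MISSING, HOM1)
        assert pair_shares(MISSING, HOM2)
        assert pair_shares(MISSING, MISSING)

    def test_exhaustive_code_table(self):
        table = [[bool(pair_shares(a, b)) for b in range(4)] for a in range(4)]
        n_false = sum(not x for row in table for x in row)
        assert n_false == 2  # only (hom1, hom2) and (hom2, hom1)
        for a in range(4):
            for b in range(4):
                assert table[a][b] == oracle_pair_shares(a, b)


class TestSharingCounts:
    def test_direct_formula(self):
        codes = np.array([[HOM1], [HOM2], [HET], [HET], [HET]], dtype=np.int8)
        assert locus_sharing_counts(codes)[0] == 4  # 5 - min(1, 1)

    def test_all_het_gives_n(self):
        codes = np.full((5, 10), HET, dtype=np.int8)
        assert (locus_sharing_counts(codes) == 5).all()

    @pytest.mark.parametrize("N, lower", [(5, 3), (10, 5)])
    def test_bounds(self, N, lower):
        """ceil(N/2) <= S_i <= N, the minimum-possible-sharing bound."""
        rng = np.random.default_rng(N)
        for _ in range(20):
            s = locus_sharing_counts(random_codes(rng, N, 50))
            assert (s >= lower).all() and (s <= N).all()


class TestRunLengths:
    def test_basic_pattern(self):
        assert run_lengths([True, True, False, True]).tolist() == [2, 2, 0, 1]

    def test_all_false(self):
        assert run_lengths([False] * 4).tolist() == [0, 0, 0, 0]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            ind = rng.random(int(rng.integers(1, 51))) < 0.6
            assert run_lengths(ind).tolist() == oracle_run_lengths(ind.tolist())

    def test_runs_stop_at_chromosome_boundaries(self):
        ind = np.ones(10, dtype=bool)
        out = run_lengths_genome(ind, np.array([0, 4, 10]))
        assert out.tolist() == [4, 4, 4, 4, 6, 6, 6, 6, 6, 6]


class TestPairwiseRuns:
    def test_identical_homozygotes_full_run(self):
        codes = np.zeros((2, 100), dtype=np.int8)
        R = pairwise_run_lengths(codes, np.array([0, 100]))
        assert (R == 100).all()

    def test_single_opposite_homozygote_splits_run(self):
        codes = np.full((2, 7), HET, dtype=np.int8)
        codes[0, 3], codes[1, 3] = HOM1, HOM2
        R = pairwise_run_lengths(codes, np.array([0, 7]))
        assert R[0].tolist() == [3, 3, 3, 0, 3, 3, 3]

    def test_matches_oracle(self):
        rng = np.random.default_rng(23)
        boundaries = np.array([0, 80, 200])
        for _ in range(10):
            codes = random_codes(rng, 4, 200)
            np.testing.assert_array_equal(
                pairwise_run_lengths(codes, boundaries),
                oracle_pairwise(codes, boundaries),
            )


class TestPsgs:
    def test_weighted_mean_arithmetic(self):
        R = np.array([[10.0], [20.0], [30.0]])
        d = np.array([2, 4, 6])
        assert psgs_statistic(R, d)[0] == pytest.approx((20 + 80 + 180) / 12)

    def test_equal_weights_reduce_to_plain_mean(self):
        rng = np.random.default_rng(1)
        R = rng.integers(0, 50, size=(6, 30)).astype(float)
        np.testing.assert_allclose(
            psgs_statistic(R, np.full(6, 5)), R.mean(axis=0)
        )

    def test_scale_invariance_of_weights(self):
        rng = np.random.default_rng(2)
        R = rng.integers(0, 50, size=(3, 20)).astype(float)
        d = np.array([2, 5, 9])
        np.testing.assert_allclose(psgs_statistic(R, d), psgs_statistic(R, d * 7))

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            psgs_statistic(np.zeros((3, 5)), np.array([1, 2]))


class TestSgs:
    def test_all_identical_heterozygotes(self):
        codes = np.full((4, 50), HET, dtype=np.int8)
        assert (sgs_statistic(codes, np.array([0, 50])) == 50).all()

    def test_one_opposite_pair_breaks_run(self):
        codes = np.full((4, 9), HET, dtype=np.int8)
        codes[0, 4], codes[1, 4] = HOM1, HOM2
        out = sgs_statistic(codes, np.array([0, 9]))
        assert out[4] == 0 and out[0] == 4 and out[8] == 4

    def test_matches_oracle(self):
        rng = np.random.default_rng(31)
        boundaries = np.array([0, 60, 120])
        for _ in range(10):
            codes = random_codes(rng, 5, 120, p_missing=0.2)
            np.testing.assert_array_equal(
                sgs_statistic(codes, boundaries), oracle_sgs(codes, boundaries)
            )

    def test_threshold_runs_non_increasing_in_t(self):
        rng = np.random.default_rng(37)
        codes = random_codes(rng, 6, 100)
        b = np.array([0, 100])
        prev = threshold_run_lengths(codes, b, 3)
        for t in (4, 5, 6):
            cur = threshold_run_lengths(codes, b, t)
            assert (cur <= prev).all()
            prev = cur


class TestTwoPedigree:
    def test_single_pair_reduces_to_pairwise_run(self):
        rng = np.random.default_rng(3)
        codes = random_codes(rng, 2, 50)
        b = np.array([0, 50])
        np.testing.assert_allclose(
            two_pedigree_statistic(codes, b),
            pairwise_run_lengths(codes, b)[0].astype(float),
        )

    def test_pair_count_for_fifteen_cases(self):
        codes = np.full((15, 10), HET, dtype=np.int8)
        b = np.array([0, 10])
        R = pairwise_run_lengths(codes, b)
        assert R.shape[0] == 105  # C(15, 2)
        np.testing.assert_allclose(two_pedigree_statistic(codes, b), 10.0)

    def test_matches_oracle(self):
        rng = np.random.default_rng(41)
        b = np.array([0, 90])
        for _ in range(10):
            codes = random_codes(rng, 5, 90)
            np.testing.assert_allclose(
                two_pedigree_statistic(codes, b),
                oracle_pairwise(codes, b).mean(axis=0),
            )


class TestInvariances:
    def test_case_order_and_allele_relabeling(self):
        """Statistics are invariant to case order and to swapping allele
        labels 1<->2 at any subset of SNPs."""
        rng = np.random.default_rng(53)
        codes = random_codes(rng, 6, 80)
        b = np.array([0, 80])
        d = rng.integers(2, 12, size=15)
        base_p = psgs_statistic(pairwise_run_lengths(codes, b), np.ones(15))
        base_s = sgs_statistic(codes, b)
        perm = rng.permutation(6)
        flipped = codes[perm].copy()
        flip = rng.random(80) < 0.5
        swap = flipped[:, flip]
        swap[swap == HOM1] = 5
        swap[swap == HOM2] = HOM1
        swap[swap == 5] = HOM2
        flipped[:, flip] = swap
        np.testing.assert_allclose(
            psgs_statistic(pairwise_run_lengths(flipped, b), np.ones(15)), base_p
        )
        np.testing.assert_array_equal(sgs_statistic(flipped, b), base_s)

    def test_full_sharing_everywhere_equalizes_statistics(self):
        codes = np.full((5, 40), HET, dtype=np.int8)
        b = np.array([0, 40])
        d = np.array([2, 4, 4, 6, 6, 8, 8, 2, 4, 6])
        psgs = psgs_statistic(pairwise_run_lengths(codes, b), d)
        sgs = sgs_statistic(codes, b)
        assert (psgs == 40).all() and (sgs == 40).all()


class TestRegionSummary:
    def test_constant_sharing(self):
        codes = np.array([[HOM1], [HET], [HET], [HET], [HET]], dtype=np.int8)
        codes = np.repeat(codes, 6, axis=1)
        assert region_sharing_summary(codes, np.arange(6)) == (5.0, 5, 5)

    def test_mixed_region(self):
        # S per locus = [3, 5, 5, 5] for 5 cases
        cols = []
        cols.append([HOM1, HOM1, HOM2, HOM2, HET])  # S = 5 - min(2,2) = 3
        for _ in range(3):
            cols.append([HET] * 5)
        codes = np.array(cols, dtype=np.int8).T
        mean, lo, hi = region_sharing_summary(codes, np.arange(4))
        assert (mean, lo, hi) == (4.5, 3, 5)

    def test_random_region_matches_tally(self):
        rng = np.random.default_rng(61)
        codes = random_codes(rng, 7, 50)
        loci = rng.choice(50, size=12, replace=False)
        mean, lo, hi = region_sharing_summary(codes, loci)
        s = locus_sharing_counts(codes)[loci]
        assert mean == pytest.approx(s.mean())
        assert (lo, hi) == (s.min(), s.max())

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_sharing_summary(np.full((3, 5), HET, dtype=np.int8), [])
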