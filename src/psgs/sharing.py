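"""Per-locus IBS sharing counts, run lengths, and the SGS / pSGS statistics.

At a biallelic SNP, IBS sharing between two cases is impossible only when
they are opposite homozygotes; missing genotypes are treated as
heterozygotes (which always share). For N cases the sharing count is
``S_i = N - min(N11_i, N22_i)``, so ceil(N/2) <= S_i <= N.

Run lengths count consecutive SNPs, never spanning a chromosome boundary:
``R_i(t)`` is the length of the maximal run containing SNP i on which at
least t cases share (t = N gives the all-share SGS statistic), and
``R_i^jk(2)`` the analogous pairwise run for cases j, k. The weighted
pairwise statistic is

    pSGS_i = sum_pairs d_jk * R_i^jk(2) / sum_pairs d_jk

a weighted mean over all case pairs with meiosis-count weights, so pairs of
distant relatives (whose long shared runs are more surprising) count more.
Cases drawn from two pedigrees with no genealogical link have no defined
d_jk, so the two-pedigree statistic is the unweighted mean over all pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .genotypes import HET, HOM1, HOM2, MISSING
from .pedigree import PairWeightMatrix

__all__ = [
    "pair_shares",
    "locus_sharing_counts",
    "run_lengths",
    "run_lengths_genome",
    "pairwise_run_lengths",
    "psgs_statistic",
    "sgs_statistic",
    "threshold_run_lengths",
    "two_pedigree_statistic",
    "region_sharing_summary",
]


def _as_het(codes: np.ndarray) -> np.ndarray:
    """Missing -> heterozygote, applied only inside sharing computations."""
    return np.where(codes == MISSING, np.int8(HET), codes)


def pair_shares(code_j, code_k):
    """IBS sharing indicator for a pair of genotype codes (vectorized).

    False exactly when one code is hom-1 and the other hom-2 after the
    missing-as-het convention.
    """
    cj = _as_het(np.asarray(code_j, dtype=np.int8))
    ck = _as_het(np.asarray(code_k, dtype=np.int8))
    return ~(((cj == HOM1) & (ck == HOM2)) | ((cj == HOM2) & (ck == HOM1)))


def locus_sharing_counts(codes: np.ndarray) -> np.ndarray:
    """S_i = N - min(N11_i, N22_i) for case codes of shape (N, L)."""
    codes = _as_het(np.asarray(codes, dtype=np.int8))
    n11 = (codes == HOM1).sum(axis=0)
    n22 = (codes == HOM2).sum(axis=0)
    return codes.shape[0] - np.minimum(n11, n22)


def run_lengths(indicator: np.ndarray) -> np.ndarray:
    """Per-locus length of the maximal run of True containing each locus.

    Accepts (..., L); the last axis is one chromosome. Loci where the
    indicator is False report 0; every locus inside a run reports the run's
    full length.
    """
    ind = np.asarray(indicator, dtype=bool)
    shape = ind.shape
    flat = ind.reshape(-1, shape[-1])
    out = np.zeros_like(flat, dtype=np.int64)
    for r in range(flat.shape[0]):
        row = flat[r]
        padded = np.concatenate([[False], row, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            out[r, s:e] = e - s
    return out.reshape(shape)


def run_lengths_genome(indicator: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Run lengths over a concatenated genome; runs stop at chromosome
    boundaries (``boundaries`` = chromosome start offsets plus total)."""
    ind = np.asarray(indicator, dtype=bool)
    out = np.empty(ind.shape, dtype=np.int64)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        out[..., a:b] = run_lengths(ind[..., a:b])
    return out


def case_pairs(case_ids) -> list[tuple[str, str]]:
    return list(combinations(case_ids, 2))


def pairwise_run_lengths(
    codes: np.ndarray, boundaries: np.ndarray
) -> np.ndarray:
    """R_i^jk(2) for all unordered case pairs.

    ``codes`` is (N, L); returns (n_pairs, L) with pairs ordered as
    ``itertools.combinations(range(N), 2)``.
    """
    N = codes.shape[0]
    pairs = list(combinations(range(N), 2))
    share = np.stack([pair_shares(codes[j], codes[k]) for j, k in pairs])
    return run_lengths_genome(share, boundaries)


def psgs_statistic(pair_runs: np.ndarray, weights: PairWeightMatrix | np.ndarray):
    """Weighted mean of pairwise run lengths: sum(d*R)/sum(d) per locus."""
    d = weights.d if isinstance(weights, PairWeightMatrix) else np.asarray(weights)
    d = d.astype(float)
    if pair_runs.shape[0] != len(d):
        raise ValueError(
            f"{pair_runs.shape[0]} pair tracks but {len(d)} weights; "
            "weights must cover exactly the case pairs present"
        )
    return d @ pair_runs / d.sum()


def threshold_run_lengths(
    codes: np.ndarray, boundaries: np.ndarray, t: int
) -> np.ndarray:
    """R_i(t): run lengths of the at-least-t-cases-share indicator."""
    s = locus_sharing_counts(codes)
    return run_lengths_genome(s >= t, boundaries)


def sgs_statistic(codes: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """All-share SGS statistic R_i(N) per locus."""
    return threshold_run_lengths(codes, boundaries, codes.shape[0])


def two_pedigree_statistic(codes: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Unweighted mean pairwise run length over all pairs of the combined
    case set (within- and cross-pedigree pairs alike)."""
    if codes.shape[0] < 2:
        raise ValueError("need at least 2 cases in the combined set")
    return pairwise_run_lengths(codes, boundaries).mean(axis=0)


def region_sharing_summary(codes: np.ndarray, region_loci) -> tuple[float, int, int]:
    """(mean, min, max) of S_i across a region's loci."""
    region_loci = np.asarray(region_loci)
    if region_loci.size == 0:
        raise ValueError("region has no loci")
    s = locus_sharing_counts(codes)[region_loci]
    return float(s.mean()), int(s.min()), int(s.max())
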