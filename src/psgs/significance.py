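"""Empirical p-values, region calling, mu rates, and genomewide thresholds.

Observed statistics are compared locus by locus to a Monte Carlo null built
by gene-dropping: p = (1 + #{null >= observed}) / (1 + n_null), the add-one
correction keeping p > 0 with finite replicates. Nominal regions are
maximal runs of loci with p <= alpha (default 0.05), reported by the bp of
their first and last locus.

Genomewide thresholds correct for the number of independent segments a
pedigree's meiotic structure produces: G extra null genomes are scanned
exactly like observed data, every called segment's p-value is pooled, and
the threshold expected to be crossed ``rate`` times per genome under the
null is the value at rank round(rate * G) of the ascending pooled list
(rank 50 of G=1,000 for the significant threshold mu=0.05, rank 1,000 for
the suggestive mu=1.0). The mu rate of an observed p is the pooled count of
null segment p-values at or below it, divided by G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genedrop import GeneticMapView, drop_genomes, mask_to_observed_missing
from .ldmodel import HaplotypeLDModel
from .pedigree import Pedigree
from .sharing import (
    locus_sharing_counts,
    pairwise_run_lengths,
    psgs_statistic,
    sgs_statistic,
    two_pedigree_statistic,
)

__all__ = [
    "NullStatisticStore",
    "RegionCall",
    "ThresholdEstimate",
    "empirical_p",
    "empirical_p_track",
    "call_regions",
    "intersect_regions",
    "rank_threshold",
    "genomewide_thresholds",
    "mu_rate",
    "statistic_track",
    "build_null_store",
    "regions_to_bed",
    "regions_to_table",
]


# -- statistic tracks -------------------------------------------------------


def statistic_track(
    codes: np.ndarray, boundaries: np.ndarray, kind: str, weights=None
) -> np.ndarray:
    """Per-locus statistic of one genotype configuration (N, L)."""
    if kind == "psgs":
        return psgs_statistic(pairwise_run_lengths(codes, boundaries), weights)
    if kind == "sgs":
        return sgs_statistic(codes, boundaries).astype(float)
    if kind == "two-pedigree":
        return two_pedigree_statistic(codes, boundaries)
    raise ValueError(f"unknown statistic kind {kind!r}")


@dataclass
class NullStatisticStore:
    """Per-locus null statistic values from gene-dropping replicates.

    ``values`` is (n_null, L); a per-column ascending sort is cached for
    fast counting. The default comparison is per-locus (each locus against
    its own null distribution); ``pooled=True`` compares every locus to the
    genomewide pool instead.
    """

    kind: str
    values: np.ndarray
    seed: int | None = None
    pooled: bool = False
    _sorted: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("null store needs (n_null, L) with n_null >= 1")
        if np.any(self.values < 0):
            raise ValueError("null statistic values must be >= 0")
        if self.pooled:
            self._sorted = np.sort(self.values, axis=None)
        else:
            self._sorted = np.sort(self.values, axis=0)

    @property
    def n_null(self) -> int:
        return self.values.shape[0]

    def p_track(self, observed: np.ndarray) -> np.ndarray:
        """Empirical p per locus with the add-one correction."""
        observed = np.asarray(observed, dtype=float)
        if self.pooled:
            n = self._sorted.size
            ge = n - np.searchsorted(self._sorted, observed, side="left")
            return (1.0 + ge) / (1.0 + n)
        L = self.values.shape[1]
        if len(observed) != L:
            raise ValueError("observed track length does not match the store")
        ge = np.empty(L, dtype=np.int64)
        for i in range(L):
            ge[i] = self.n_null - np.searchsorted(
                self._sorted[:, i], observed[i], side="left"
            )
        return (1.0 + ge) / (1.0 + self.n_null)


def build_null_store(
    ped: Pedigree,
    model: HaplotypeLDModel,
    gmap: GeneticMapView,
    n_null: int,
    seed: int,
    kind: str = "psgs",
    weights=None,
    boundaries: np.ndarray | None = None,
    observed=None,
    mask_missing: bool = True,
) -> NullStatisticStore:
    """Gene-drop ``n_null`` replicates and record the statistic track of each.

    If ``observed`` (a case GenotypeMatrix) is given and ``mask_missing``
    is on, null genotypes are masked to missing at observed-missing loci so
    the null statistics see identical missingness.
    """
    if boundaries is None:
        sizes = [gmap.n_snps(c) for c in gmap.chromosomes()]
        boundaries = np.concatenate([[0], np.cumsum(sizes)])
    drops = drop_genomes(ped, model, gmap, n_null, seed)
    codes = drops.codes
    if observed is not None and mask_missing:
        codes = mask_to_observed_missing(codes, observed, ped.case_ids)
    vals = np.empty((n_null, codes.shape[2]))
    for r in range(n_null):
        vals[r] = statistic_track(codes[r], boundaries, kind, weights)
    return NullStatisticStore(kind=kind, values=vals, seed=seed)


# -- empirical p ------------------------------------------------------------


def empirical_p(observed: float, null_values) -> float:
    """p = (1 + #{null >= observed}) / (1 + n_null)."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null collection is empty")
    return float((1 + (null_values >= observed).sum()) / (1 + null_values.size))


def empirical_p_track(observed: np.ndarray, store: NullStatisticStore) -> np.ndarray:
    return store.p_track(observed)


# -- regions ----------------------------------------------------------------


@dataclass
class RegionCall:
    """A maximal run of loci at nominal significance (1-based inclusive bp)."""

    chrom: str
    start_bp: int
    end_bp: int
    best_p: float
    n_loci: int = 0
    loci: np.ndarray | None = None  # indices into the genomewide SNP table
    mu: float | None = None
    sharing_mean: float | None = None
    sharing_min: int | None = None
    sharing_max: int | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start after end")

    @property
    def length_mb(self) -> float:
        return round((self.end_bp - self.start_bp) / 1e6, 1)


def call_regions(
    p_track: np.ndarray, snps: pd.DataFrame, alpha: float = 0.05
) -> list[RegionCall]:
    """Maximal runs of loci with p <= alpha, one RegionCall each."""
    p_track = np.asarray(p_track, dtype=float)
    if len(p_track) != len(snps):
        raise ValueError("p-track and SNP table lengths differ")
    regions: list[RegionCall] = []
    chroms = snps["chrom"].to_numpy()
    bps = snps["bp"].to_numpy()
    sig = p_track <= alpha
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        padded = np.concatenate([[False], sig[idx], [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        for s, e in zip(starts, ends):
            loci = idx[s : e + 1]
            regions.append(
                RegionCall(
                    chrom=str(chrom),
                    start_bp=int(bps[loci[0]]),
                    end_bp=int(bps[loci[-1]]),
                    best_p=float(p_track[loci].min()),
                    n_loci=len(loci),
                    loci=loci,
                )
            )
    return regions


def intersect_regions(a: RegionCall, b: RegionCall) -> RegionCall | None:
    """Overlap of two same-chromosome regions, or None if disjoint."""
    if a.chrom != b.chrom:
        raise ValueError(f"regions on different chromosomes: {a.chrom} vs {b.chrom}")
    start = max(a.start_bp, b.start_bp)
    end = min(a.end_bp, b.end_bp)
    if start > end:
        return None
    return RegionCall(
        chrom=a.chrom, start_bp=start, end_bp=end, best_p=max(a.best_p, b.best_p)
    )


# -- genomewide thresholds --------------------------------------------------


@dataclass
class ThresholdEstimate:
    kind: str
    suggestive: float | None  # crossed ~1.0 times per genome under the null
    significant: float | None  # crossed ~0.05 times per genome
    n_genomes: int
    pooled_segment_ps: np.ndarray  # ascending

    def __post_init__(self) -> None:
        if (
            self.suggestive is not None
            and self.significant is not None
            and self.significant > self.suggestive
        ):
            raise ValueError("significant threshold must be <= suggestive")


def rank_threshold(pooled_ps, n_genomes: int, rate: float) -> float | None:
    """Value at rank round(rate * G), 1-indexed, of the ascending pooled
    segment p-values; None when fewer segments than the rank exist."""
    pooled = np.sort(np.asarray(pooled_ps, dtype=float))
    r = int(round(rate * n_genomes))
    if r < 1 or r > len(pooled):
        return None
    return float(pooled[r - 1])


def genomewide_thresholds(
    ped: Pedigree,
    model: HaplotypeLDModel,
    gmap: GeneticMapView,
    store: NullStatisticStore,
    snps: pd.DataFrame,
    n_genomes: int,
    seed: int,
    kind: str = "psgs",
    weights=None,
    alpha: float = 0.05,
    observed=None,
    mask_missing: bool = True,
) -> ThresholdEstimate:
    """Estimate suggestive (mu=1.0) and significant (mu=0.05) thresholds.

    Scans ``n_genomes`` fresh null genomes against the shared inner null
    ``store``, calls nominal regions in each, pools every region's best
    (minimum per-locus) p-value, and reads thresholds off the ranked pool.
    """
    if n_genomes < 20:
        raise ValueError("need at least 20 null genomes for thresholds")
    sizes = [gmap.n_snps(c) for c in gmap.chromosomes()]
    boundaries = np.concatenate([[0], np.cumsum(sizes)])
    drops = drop_genomes(ped, model, gmap, n_genomes, seed)
    codes = drops.codes
    if observed is not None and mask_missing:
        codes = mask_to_observed_missing(codes, observed, ped.case_ids)
    pooled: list[float] = []
    for g in range(n_genomes):
        track = statistic_track(codes[g], boundaries, kind, weights)
        p = store.p_track(track)
        for region in call_regions(p, snps, alpha):
            pooled.append(region.best_p)
    pooled_arr = np.sort(np.asarray(pooled, dtype=float))
    return ThresholdEstimate(
        kind=kind,
        suggestive=rank_threshold(pooled_arr, n_genomes, 1.0),
        significant=rank_threshold(pooled_arr, n_genomes, 0.05),
        n_genomes=n_genomes,
        pooled_segment_ps=pooled_arr,
    )


def mu_rate(observed_p: float, pooled_segment_ps, n_genomes: int) -> float:
    """Expected null findings per genome at least as extreme as observed_p."""
    pooled = np.asarray(pooled_segment_ps, dtype=float)
    return float((pooled <= observed_p).sum() / n_genomes)


# -- exports ----------------------------------------------------------------


def annotate_regions(
    regions: list[RegionCall],
    codes: np.ndarray,
    thresholds: ThresholdEstimate | None = None,
) -> list[RegionCall]:
    """Fill sharing summaries (and mu, when thresholds are given) in place."""
    for region in regions:
        if region.loci is not None:
            s = locus_sharing_counts(codes)[region.loci]
            region.sharing_mean = float(s.mean())
            region.sharing_min = int(s.min())
            region.sharing_max = int(s.max())
        if thresholds is not None:
            region.mu = mu_rate(
                region.best_p, thresholds.pooled_segment_ps, thresholds.n_genomes
            )
    return regions


def regions_to_bed(regions: list[RegionCall], path) -> None:
    """BED export: 0-based half-open, score = -log10(best p)."""
    with open(path, "w") as fh:
        for r in regions:
            score = -np.log10(r.best_p)
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t.\t{score:.4f}\n")


def regions_to_table(regions: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "region": [f"{r.start_bp} - {r.end_bp}" for r in regions],
            "length_mb": [r.length_mb for r in regions],
            "best_p": [r.best_p for r in regions],
            "mu": [r.mu for r in regions],
            "sharing_mean": [r.sharing_mean for r in regions],
            "sharing_min": [r.sharing_min for r in regions],
            "sharing_max": [r.sharing_max for r in regions],
            "n_loci": [r.n_loci for r in regions],
        }
    )
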