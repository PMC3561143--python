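"""Gene-dropping: null genotypes for pedigree cases by simulated descent.

Founder haplotypes drawn from the LD model are segregated through the
pedigree under Mendelian inheritance. Crossovers follow a homogeneous
Poisson process at rate 1 per Morgan along the genetic-map coordinate
(Haldane: no interference), each chromosome independently. Genotypes are
retained only for the studied cases; optional IBD tracing labels every
transmitted allele with the founder gamete it descends from, which is what
the segment-length checks against the Exp(1/d) and Gamma(mean 2/d) laws
consume.

Two entry points: :func:`drop_genome` performs one replicate with explicit
crossover positions; :func:`drop_genomes` batches replicates using the
equivalent per-interval switch probabilities 0.5*(1 - exp(-2*delta))
(identical law at SNP resolution, vectorized over replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING
from .ldmodel import HaplotypeLDModel
from .pedigree import Pedigree

__all__ = [
    "GeneticMapView",
    "DropResult",
    "sample_gamete",
    "drop_genome",
    "drop_genomes",
    "pair_ibd_indicator",
    "ibd_segments",
    "segment_lengths_cm",
    "mask_to_observed_missing",
]


@dataclass
class GeneticMapView:
    """Ordered cM positions per chromosome (sex-averaged map)."""

    cm: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.cm.items():
            pos = np.asarray(pos, dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"cM positions decrease on chromosome {chrom}")
            self.cm[chrom] = pos

    @classmethod
    def from_snps(cls, snps: pd.DataFrame) -> "GeneticMapView":
        return cls(
            cm={
                str(chrom): grp["cm"].to_numpy(dtype=float)
                for chrom, grp in snps.groupby("chrom", sort=False)
            }
        )

    def chromosomes(self) -> list[str]:
        return list(self.cm)

    def n_snps(self, chrom: str) -> int:
        return len(self.cm[chrom])

    def morgans(self, chrom: str) -> float:
        pos = self.cm[chrom]
        return float(pos[-1] - pos[0]) / 100.0

    def total_morgans(self) -> float:
        return sum(self.morgans(c) for c in self.cm)

    def switch_probs(self, chrom: str) -> np.ndarray:
        """P(odd crossover count) in each inter-SNP interval (Haldane)."""
        d = np.diff(self.cm[chrom]) / 100.0
        return 0.5 * (1.0 - np.exp(-2.0 * d))


# -- single-gamete sampling -------------------------------------------------


def _active_haplotype(cm: np.ndarray, rng: np.random.Generator):
    """Explicit crossover draw: which parental haplotype (0/1) is copied at
    each SNP, plus the crossover count."""
    total_m = (cm[-1] - cm[0]) / 100.0
    k = rng.poisson(total_m)
    xpos = np.sort(rng.uniform(cm[0], cm[-1], size=k))
    start = int(rng.integers(2))
    active = (start + np.searchsorted(xpos, cm, side="right")) % 2
    return active.astype(np.int8), k


def sample_gamete(
    parent_haplotypes: np.ndarray,
    cm: np.ndarray,
    rng: np.random.Generator,
    return_crossovers: bool = False,
):
    """One meiotic product of a pair of parental haplotypes.

    ``parent_haplotypes`` is (2, L); the starting haplotype is chosen with
    probability 1/2 and switches at each Poisson(rate 1/Morgan) crossover.
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 2 or haps.shape[0] != 2 or haps.shape[1] != len(cm):
        raise ValueError("parent haplotypes must be (2, L) covering the map")
    active, k = _active_haplotype(np.asarray(cm, dtype=float), rng)
    gamete = haps[active, np.arange(haps.shape[1])]
    if return_crossovers:
        return gamete, k
    return gamete


# -- drop results -----------------------------------------------------------


@dataclass
class DropResult:
    """Case genotypes (and optional founder-gamete labels) from one drop."""

    case_ids: list[str]
    codes: np.ndarray  # (N, L_total) int8
    labels: np.ndarray | None = None  # (N, 2, L_total) founder gamete ids
    seed: int | None = None


def _founder_gamete_ids(ped: Pedigree) -> dict[str, tuple[int, int]]:
    return {f: (2 * i, 2 * i + 1) for i, f in enumerate(ped.founders)}


def drop_genome(
    ped: Pedigree,
    model: HaplotypeLDModel,
    gmap: GeneticMapView,
    seed: int,
    trace_ibd: bool = False,
) -> DropResult:
    """One gene-dropping replicate with explicit crossover positions."""
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    gids = _founder_gamete_ids(ped)
    chrom_codes, chrom_labels = [], []
    for chrom in gmap.chromosomes():
        cm = gmap.cm[chrom]
        L = len(cm)
        founder_haps = model.sample(chrom, 2 * len(gids), rng)
        haps: dict[str, np.ndarray] = {}
        labs: dict[str, np.ndarray] = {}
        for f, (g0, g1) in gids.items():
            haps[f] = founder_haps[[g0, g1]]
            labs[f] = np.array([np.full(L, g0), np.full(L, g1)], dtype=np.int16)
        for iid in order:
            ind = ped.individuals[iid]
            if ind.is_founder:
                continue
            h, lab = [], []
            for parent in (ind.father, ind.mother):
                active, _ = _active_haplotype(cm, rng)
                ar = np.arange(L)
                h.append(haps[parent][active, ar])
                lab.append(labs[parent][active, ar])
            haps[iid] = np.array(h, dtype=np.int8)
            labs[iid] = np.array(lab, dtype=np.int16)
        chrom_codes.append(
            np.array([haps[c][0] + haps[c][1] for c in ped.case_ids], dtype=np.int8)
        )
        if trace_ibd:
            chrom_labels.append(np.array([labs[c] for c in ped.case_ids]))
    return DropResult(
        case_ids=list(ped.case_ids),
        codes=np.concatenate(chrom_codes, axis=1),
        labels=np.concatenate(chrom_labels, axis=2) if trace_ibd else None,
        seed=seed,
    )


def drop_genomes(
    ped: Pedigree,
    model: HaplotypeLDModel | None,
    gmap: GeneticMapView,
    n_reps: int,
    seed: int,
    trace_ibd: bool = False,
) -> DropResult:
    """Batched gene-dropping over ``n_reps`` replicates.

    Returns a :class:`DropResult` whose arrays carry a leading replicate
    axis: codes (n_reps, N, L) and labels (n_reps, N, 2, L). ``model`` may
    be None when only IBD labels are needed (codes are then all-missing),
    which skips founder haplotype content entirely.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    gids = _founder_gamete_ids(ped)
    n_founders = len(gids)
    N = ped.n_cases
    out_codes, out_labels = [], []
    for chrom in gmap.chromosomes():
        cm = gmap.cm[chrom]
        L = len(cm)
        psw = np.concatenate([[0.0], 0.5 * (1.0 - np.exp(-2.0 * np.diff(cm) / 100.0))])
        haps: dict[str, np.ndarray] = {}
        labs: dict[str, np.ndarray] = {}
        if model is not None:
            fh = model.sample(chrom, n_reps * 2 * n_founders, rng)
            fh = fh.reshape(n_reps, 2 * n_founders, L)
        for f, (g0, g1) in gids.items():
            if model is not None:
                haps[f] = fh[:, [g0, g1], :]
            if trace_ibd:
                lab = np.empty((n_reps, 2, L), dtype=np.int16)
                lab[:, 0, :] = g0
                lab[:, 1, :] = g1
                labs[f] = lab
        for iid in order:
            ind = ped.individuals[iid]
            if ind.is_founder:
                continue
            h = np.empty((n_reps, 2, L), dtype=np.int8) if model is not None else None
            lab = np.empty((n_reps, 2, L), dtype=np.int16) if trace_ibd else None
            for g, parent in enumerate((ind.father, ind.mother)):
                start = rng.integers(0, 2, size=(n_reps, 1))
                switch = rng.random((n_reps, L)) < psw[None, :]
                switch[:, 0] = 0
                active = (start + np.cumsum(switch, axis=1)) % 2
                idx = active[:, None, :]
                if model is not None:
                    h[:, g, :] = np.take_along_axis(haps[parent], idx, axis=1)[:, 0, :]
                if trace_ibd:
                    lab[:, g, :] = np.take_along_axis(labs[parent], idx, axis=1)[
                        :, 0, :
                    ]
            if model is not None:
                haps[iid] = h
            if trace_ibd:
                labs[iid] = lab
        if model is not None:
            codes = np.empty((n_reps, N, L), dtype=np.int8)
            for c, cid in enumerate(ped.case_ids):
                codes[:, c, :] = haps[cid].sum(axis=1, dtype=np.int8)
        else:
            codes = np.full((n_reps, N, L), MISSING, dtype=np.int8)
        out_codes.append(codes)
        if trace_ibd:
            out_labels.append(
                np.stack([labs[cid] for cid in ped.case_ids], axis=1)
            )
    return DropResult(
        case_ids=list(ped.case_ids),
        codes=np.concatenate(out_codes, axis=2),
        labels=np.concatenate(out_labels, axis=3) if trace_ibd else None,
        seed=seed,
    )


# -- IBD segment utilities --------------------------------------------------


def pair_ibd_indicator(labels_j: np.ndarray, labels_k: np.ndarray) -> np.ndarray:
    """True where two cases carry at least one allele from the same founder
    gamete. Inputs are (..., 2, L) label arrays; output (..., L)."""
    lj = labels_j[..., :, None, :]
    lk = labels_k[..., None, :, :]
    return np.any(lj == lk, axis=(-3, -2))


def ibd_segments(indicator: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of a boolean per-SNP indicator as (first, last) indices."""
    ind = np.asarray(indicator, dtype=bool)
    if ind.ndim != 1:
        raise ValueError("one chromosome at a time")
    padded = np.concatenate([[False], ind, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def segment_lengths_cm(
    indicator: np.ndarray, cm: np.ndarray, pad: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Segment lengths in cM and a per-segment end-censoring flag.

    The raw cM span from the first to the last SNP of a run truncates the
    true segment by on average half a marker spacing at each boundary, so
    with ``pad`` each interior boundary is extended by half the flanking
    inter-SNP gap. Segments touching a chromosome end are flagged censored.
    """
    segs = ibd_segments(indicator)
    L = len(cm)
    lengths, censored = [], []
    for i0, i1 in segs:
        length = float(cm[i1] - cm[i0])
        cens = i0 == 0 or i1 == L - 1
        if pad:
            if i0 > 0:
                length += float(cm[i0] - cm[i0 - 1]) / 2.0
            if i1 < L - 1:
                length += float(cm[i1 + 1] - cm[i1]) / 2.0
        lengths.append(length)
        censored.append(cens)
    return np.asarray(lengths, dtype=float), np.asarray(censored, dtype=bool)


def mask_to_observed_missing(
    null_codes: np.ndarray, observed: GenotypeMatrix, case_ids
) -> np.ndarray:
    """Mask null case genotypes to missing wherever the observed case
    genotype is missing, so observed and null statistics see identical
    missingness (flag-controlled upstream, default on)."""
    idx = [observed.samples.index(c) for c in case_ids]
    obs_missing = (observed.codes[:, idx] == MISSING).T  # (N, L)
    out = null_codes.copy()
    out[..., obs_missing] = MISSING
    return out
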