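"""SNP genotype containers, PLINK text PED/MAP I/O, and SNP quality control.

Genotypes are stored as small-integer codes per (SNP, sample):

====  ==========================================
code  meaning
====  ==========================================
0     homozygous for allele 1 ("11")
1     heterozygous ("12")
2     homozygous for allele 2 ("22")
3     missing
====  ==========================================

Allele 1 is the lexicographically smaller allele label at each SNP, so the
coding is reproducible from a PED file alone. QC applies the standard array
filters: differential case/control missingness, overall missing rate, minor
allele frequency, and Hardy-Weinberg equilibrium, with MAF/HWE computed on
the unrelated controls (pedigree cases violate the independence the tests
assume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HOM1, HET, HOM2, MISSING = 0, 1, 2, 3

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "read_ped_map",
    "write_ped_map",
    "read_map",
    "hwe_test",
    "filter_snps",
    "HOM1",
    "HET",
    "HOM2",
    "MISSING",
]


@dataclass
class GenotypeMatrix:
    """SNP-by-sample genotype codes plus per-SNP metadata.

    ``snps`` columns: snp_id, chrom, cm, bp, a1, a2 (allele labels; a2 may
    be None for a monomorphic SNP). SNPs are grouped by chromosome and
    sorted by bp within each chromosome.
    """

    snps: pd.DataFrame
    samples: list[str]
    codes: np.ndarray  # (n_snps, n_samples) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.snps), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
            cm = grp["cm"].to_numpy(dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease on chromosome {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.snps["chrom"]))

    def chrom_slices(self) -> dict:
        """Chromosome -> slice into the SNP axis (SNPs are chrom-grouped)."""
        out = {}
        chroms = self.snps["chrom"].to_numpy()
        start = 0
        for chrom in self.chromosomes():
            n = int((chroms == chrom).sum())
            out[chrom] = slice(start, start + n)
            start += n
        return out

    def chrom_boundaries(self) -> np.ndarray:
        """Start offsets of each chromosome plus the total SNP count."""
        sizes = [sl.stop - sl.start for sl in self.chrom_slices().values()]
        return np.concatenate([[0], np.cumsum(sizes)])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            snps=self.snps.copy(), samples=list(sample_ids), codes=self.codes[:, idx]
        )

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            snps=self.snps.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            codes=self.codes[mask],
        )


# -- PED/MAP I/O ------------------------------------------------------------


def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK MAP file (chrom, snp_id, cm, bp)."""
    snps = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": np.int64},
    )
    for chrom, grp in snps.groupby("chrom", sort=False):
        if np.any(np.diff(grp["bp"].to_numpy()) <= 0):
            raise ValueError(f"map not sorted by bp on chromosome {chrom}")
    return snps


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    Allele 1 at each SNP is the lexicographically smaller observed allele
    label; "0 0" is missing. Triallelic SNPs are an error.
    """
    snps = read_map(map_path)
    m = len(snps)
    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns for {m} SNPs, "
                    f"got {len(tokens)}"
                )
            samples.append(tokens[1])
            allele_rows.append(np.array(tokens[6:], dtype=object).reshape(m, 2))
    alleles = (
        np.stack(allele_rows, axis=2)
        if allele_rows
        else np.empty((m, 2, 0), dtype=object)
    )  # (snp, 2, sample)

    codes = np.full((m, len(samples)), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for i in range(m):
        obs = alleles[i]  # (2, n)
        present = obs != "0"
        labels = sorted(set(obs[present].tolist()))
        if len(labels) > 2:
            raise ValueError(
                f"SNP {snps['snp_id'][i]} has {len(labels)} alleles: {labels}"
            )
        a1 = labels[0] if labels else None
        a2 = labels[1] if len(labels) > 1 else None
        a1_list.append(a1)
        a2_list.append(a2)
        both = present[0] & present[1]
        n_a2 = np.zeros(obs.shape[1], dtype=np.int8)
        if a2 is not None:
            n_a2 = (obs[0] == a2).astype(np.int8) + (obs[1] == a2).astype(np.int8)
        codes[i, both] = n_a2[both]
    snps = snps.assign(a1=a1_list, a2=a2_list)
    return GenotypeMatrix(snps=snps, samples=samples, codes=codes)


def write_ped_map(genos: GenotypeMatrix, ped_path, map_path, family_id="1") -> None:
    """Write a matrix back to a PLINK text PED/MAP pair."""
    genos.snps[["chrom", "snp_id", "cm", "bp"]].to_csv(
        map_path, sep="\t", header=False, index=False
    )
    a1 = genos.snps["a1"].to_numpy(dtype=object)
    a2 = genos.snps["a2"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for s, sid in enumerate(genos.samples):
            fields = [family_id, sid, "0", "0", "0", "0"]
            col = genos.codes[:, s]
            for i in range(genos.n_snps):
                c = col[i]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == HOM1:
                    fields += [a1[i], a1[i]]
                elif c == HET:
                    fields += [a1[i], a2[i]]
                else:
                    fields += [a2[i], a2[i]]
            fh.write(" ".join(fields) + "\n")


# -- Hardy-Weinberg exact test ----------------------------------------------


def hwe_test(n11: int, n12: int, n22: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P-value is the total probability, conditional on the allele counts, of
    every heterozygote count whose probability does not exceed the observed
    one. Monomorphic sites return 1. Uses the standard two-sided "as or
    less probable" definition with probabilities built by recurrence.
    """
    n11, n12, n22 = int(n11), int(n12), int(n22)
    n = n11 + n12 + n22
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n11, n22) + n12  # copies of the rarer allele
    if rare == 0:
        return 1.0
    # unnormalized probabilities over all het counts with the allele-count parity
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(hets), dtype=float)
    probs[0] = 1.0
    for t in range(1, len(hets)):
        h = int(hets[t])
        # P(h) / P(h-2) = 4 * hom_rare(h-2) * hom_common(h-2) / (h * (h-1))
        hom_r = (rare - (h - 2)) // 2
        hom_c = n - (h - 2) - hom_r
        probs[t] = probs[t - 1] * 4.0 * hom_r * hom_c / (h * (h - 1))
        if probs[t] > 1e250:  # keep the recurrence in floating range
            probs[: t + 1] /= probs[t]
    probs /= probs.sum()
    p_obs = probs[hets == n12][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq(n11: int, n12: int, n22: int) -> float:
    """One-df chi-square HWE test (large-sample alternative to the exact test)."""
    n = n11 + n12 + n22
    p = (2 * n11 + n12) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n11, n12, n22], dtype=float)
    x2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(x2, df=1))


# -- QC filters -------------------------------------------------------------


@dataclass(frozen=True)
class QcThresholds:
    """Default SNP filters for dense array data."""

    diff_missing_p: float = 1e-5
    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    hwe_p: float = 1e-4
    exact_hwe: bool = True
    fisher_missingness: bool = True  # chi-square fallback when False


@dataclass
class QcReport:
    per_snp: pd.DataFrame
    removed_by_filter: dict[str, int]
    n_input: int
    n_retained: int

    def to_tsv(self, path) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False)


def _missing_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    miss = (codes == MISSING).sum(axis=1)
    return miss, codes.shape[1] - miss


def filter_snps(
    genos: GenotypeMatrix,
    case_ids,
    control_ids,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the four SNP filters and return the retained matrix plus report.

    Filters are evaluated independently on the input (order-independent):
    differential case/control missingness, combined missing rate, control
    MAF, and control HWE. A SNP failing any filter is removed.
    """
    th = thresholds or QcThresholds()
    if (th.min_maf > 0 or th.hwe_p > 0) and len(control_ids) == 0:
        raise ValueError("MAF/HWE filters require a non-empty control set")

    case_idx = [genos.samples.index(s) for s in case_ids]
    ctrl_idx = [genos.samples.index(s) for s in control_ids]
    cases = genos.codes[:, case_idx]
    ctrls = genos.codes[:, ctrl_idx]

    m = genos.n_snps
    miss_case, call_case = _missing_counts(cases)
    miss_ctrl, call_ctrl = _missing_counts(ctrls)
    miss_all = miss_case + miss_ctrl
    n_all = len(case_idx) + len(ctrl_idx)
    missing_rate = miss_all / n_all

    n11 = (ctrls == HOM1).sum(axis=1)
    n12 = (ctrls == HET).sum(axis=1)
    n22 = (ctrls == HOM2).sum(axis=1)
    called = n11 + n12 + n22
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = np.where(called > 0, (2 * n22 + n12) / (2 * np.maximum(called, 1)), 0.0)
    maf = np.minimum(p2, 1 - p2)

    hwe_fn = hwe_test if th.exact_hwe else hwe_chisq
    hwe_p = np.array(
        [hwe_fn(n11[i], n12[i], n22[i]) if called[i] > 0 else 1.0 for i in range(m)]
    )

    diff_p = np.ones(m)
    for i in range(m):
        table = [[miss_case[i], call_case[i]], [miss_ctrl[i], call_ctrl[i]]]
        if th.fisher_missingness:
            diff_p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
        else:
            diff_p[i] = stats.chi2_contingency(table, correction=False)[1]

    fail_diff = diff_p < th.diff_missing_p
    fail_miss = missing_rate > th.max_missing_rate
    fail_maf = maf < th.min_maf
    fail_hwe = hwe_p < th.hwe_p
    keep = ~(fail_diff | fail_miss | fail_maf | fail_hwe)

    reasons = []
    for i in range(m):
        r = []
        if fail_diff[i]:
            r.append("diff_missingness")
        if fail_miss[i]:
            r.append("missing_rate")
        if fail_maf[i]:
            r.append("maf")
        if fail_hwe[i]:
            r.append("hwe")
        reasons.append(",".join(r))

    per_snp = pd.DataFrame(
        {
            "snp_id": genos.snps["snp_id"],
            "chrom": genos.snps["chrom"],
            "bp": genos.snps["bp"],
            "missing_rate_cases": miss_case / max(len(case_idx), 1),
            "missing_rate_controls": miss_ctrl / max(len(ctrl_idx), 1),
            "missing_rate": missing_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "diff_missing_p": diff_p,
            "pass": keep,
            "fail_reasons": reasons,
        }
    )
    report = QcReport(
        per_snp=per_snp,
        removed_by_filter={
            "diff_missingness": int(fail_diff.sum()),
            "missing_rate": int(fail_miss.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        n_input=m,
        n_retained=int(keep.sum()),
    )
    return genos.subset_snps(keep), report
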