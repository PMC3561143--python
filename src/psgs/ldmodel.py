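"""Order-k Markov haplotype model with inter-marker LD.

The empirical null for segment sharing must respect local LD: founder
haplotypes that ignore allelic association would make long IBS runs look
rarer under the null than they are, inflating significance. This module
estimates, from unrelated control genotypes, a Markov chain over alleles
along each chromosome — P(allele at SNP i | previous k alleles) — and
samples founder haplotypes from it. An order-1 chain captures the dominant
serial component of LD on dense arrays; higher orders are available via
``order=k``.

Fitting resolves genotype phase ambiguity by expectation-maximization over
sliding windows of k+1 SNPs (the classic two-locus EM when k=1), then
converts window haplotype frequencies to transition probabilities with
pseudocount smoothing so no transition is exactly 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, HET, HOM1, HOM2, MISSING

__all__ = [
    "ChromLDModel",
    "HaplotypeLDModel",
    "fit_markov_ld",
    "window_em",
    "sample_haplotype",
]

_FORMAT_VERSION = 1


def window_em(
    gcodes: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """EM haplotype-frequency estimate for one window of w SNPs.

    ``gcodes``: (n, w) genotype codes with missing allowed. Returns
    ``(freqs, logliks)`` where ``freqs`` has length 2**w (haplotypes
    encoded with the window's first SNP as the highest bit) and
    ``logliks`` is the per-iteration log-likelihood trace (non-decreasing,
    an EM guarantee that the tests assert).
    """
    gcodes = np.asarray(gcodes, dtype=np.int8)
    n, w = gcodes.shape
    H = 2**w
    haps = np.arange(H)
    bits = ((haps[:, None] >> np.arange(w - 1, -1, -1)[None, :]) & 1).astype(np.int8)

    # group individuals by genotype pattern, enumerate compatible ordered pairs
    patterns, counts = np.unique(gcodes, axis=0, return_counts=True)
    pair_lists = []
    informative = 0
    for pat, cnt in zip(patterns, counts):
        if np.all(pat == MISSING):
            continue
        ok1 = np.ones(H, dtype=bool)
        pairs = []
        for h1 in range(H):
            for h2 in range(h1, H):
                s = bits[h1] + bits[h2]
                het = bits[h1] != bits[h2]
                compatible = True
                for j in range(w):
                    c = pat[j]
                    if c == MISSING:
                        continue
                    if c == HET:
                        if not het[j]:
                            compatible = False
                            break
                    elif s[j] != (0 if c == HOM1 else 2):
                        compatible = False
                        break
                if compatible:
                    pairs.append((h1, h2, 2.0 if h1 != h2 else 1.0))
        pair_lists.append((np.array(pairs, dtype=float), float(cnt)))
        informative += int(cnt)
    if informative == 0:
        raise ValueError("window has no informative genotypes")

    if init is None:
        # linkage-equilibrium start from marginal allele frequencies
        marg = np.empty(w)
        for j in range(w):
            col = gcodes[:, j]
            called = col != MISSING
            if called.sum() == 0:
                marg[j] = 0.5
            else:
                marg[j] = col[called].astype(float).sum() / (2.0 * called.sum())
        marg = np.clip(marg, 1e-6, 1 - 1e-6)
        f = np.prod(np.where(bits == 1, marg, 1 - marg), axis=1)
    else:
        f = np.asarray(init, dtype=float).copy()
    f /= f.sum()

    logliks = []
    for _ in range(max_iter):
        new = np.zeros(H)
        ll = 0.0
        for pairs, cnt in pair_lists:
            h1 = pairs[:, 0].astype(int)
            h2 = pairs[:, 1].astype(int)
            wts = pairs[:, 2] * f[h1] * f[h2]
            tot = wts.sum()
            if tot <= 0:
                continue
            ll += cnt * np.log(tot)
            wts = wts / tot * cnt
            np.add.at(new, h1, wts)
            np.add.at(new, h2, wts)
        logliks.append(ll)
        new /= new.sum()
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f, logliks


@dataclass
class ChromLDModel:
    """Markov allele model for one chromosome.

    ``probs[i]`` has shape ``(2**min(i, order),)`` and gives
    P(allele_i = allele-2 | context), the context being the previous
    ``min(i, order)`` alleles encoded as an integer with the oldest allele
    in the highest bit.
    """

    snp_ids: list[str]
    order: int
    probs: list[np.ndarray]
    alleles: list[tuple[str | None, str | None]]

    def __post_init__(self) -> None:
        if len(self.probs) != len(self.snp_ids):
            raise ValueError("probs/snp count mismatch")
        for i, p in enumerate(self.probs):
            expect = 2 ** min(i, self.order)
            if len(p) != expect:
                raise ValueError(f"probs[{i}] has length {len(p)}, expected {expect}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` haplotypes as an (n, L) array of allele codes 0/1."""
        L = self.n_snps
        out = np.empty((n, L), dtype=np.int8)
        mask = (1 << self.order) - 1
        ctx = np.zeros(n, dtype=np.int64)
        for i in range(L):
            p = self.probs[i][ctx]
            a = (rng.random(n) < p).astype(np.int8)
            out[:, i] = a
            ctx = ((ctx << 1) | a) & mask
        return out

    def forward_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Implied per-SNP allele-2 marginals and adjacent-pair joint
        frequencies (L-1, 2, 2) under the chain."""
        L = self.n_snps
        marg = np.empty(L)
        pair = np.zeros((max(L - 1, 0), 2, 2))
        mask = (1 << self.order) - 1
        dist = {0: 1.0}  # context -> probability
        for i in range(L):
            p1 = 0.0
            new: dict[int, float] = {}
            for ctx, w in dist.items():
                p = float(self.probs[i][ctx])
                p1 += w * p
                for a, wa in ((0, w * (1 - p)), (1, w * p)):
                    if wa == 0.0:
                        continue
                    nctx = ((ctx << 1) | a) & mask
                    new[nctx] = new.get(nctx, 0.0) + wa
            marg[i] = p1
            if i + 1 < L:
                # joint over (a_i, a_{i+1}): a_i is the lowest bit of the new ctx
                for ctx, w in new.items():
                    a_i = ctx & 1
                    p_next = float(self.probs[i + 1][ctx])
                    pair[i, a_i, 0] += w * (1 - p_next)
                    pair[i, a_i, 1] += w * p_next
            dist = new
        return marg, pair


@dataclass
class HaplotypeLDModel:
    """Per-chromosome Markov haplotype models (ordered as in the map)."""

    chroms: dict[str, ChromLDModel]
    order: int

    def sample(self, chrom: str, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.chroms[chrom].sample(n, rng)

    def sample_genome(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Concatenated haplotypes over every chromosome, (n, total SNPs)."""
        return np.concatenate(
            [self.chroms[c].sample(n, rng) for c in self.chroms], axis=1
        )

    @property
    def n_snps(self) -> int:
        return sum(m.n_snps for m in self.chroms.values())

    def to_json(self, path) -> None:
        doc = {
            "format": "psgs-ld-model",
            "version": _FORMAT_VERSION,
            "order": self.order,
            "chromosomes": {
                chrom: {
                    "snp_ids": m.snp_ids,
                    "alleles": [list(a) for a in m.alleles],
                    "probs": [p.tolist() for p in m.probs],
                }
                for chrom, m in self.chroms.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "HaplotypeLDModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "psgs-ld-model":
            raise ValueError(f"{path} is not an LD model file")
        if doc.get("version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported LD model version {doc.get('version')}")
        order = doc["order"]
        chroms = {
            chrom: ChromLDModel(
                snp_ids=blk["snp_ids"],
                order=order,
                probs=[np.asarray(p, dtype=float) for p in blk["probs"]],
                alleles=[tuple(a) for a in blk["alleles"]],
            )
            for chrom, blk in doc["chromosomes"].items()
        }
        return cls(chroms=chroms, order=order)


def fit_markov_ld(
    panel: GenotypeMatrix,
    order: int = 1,
    pseudocount: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_controls: int = 30,
) -> HaplotypeLDModel:
    """Fit the order-k Markov LD model from an unrelated control panel.

    Each SNP's conditional distribution comes from an EM haplotype-frequency
    fit on the window of the SNP and its k predecessors; ``pseudocount`` is
    added per window haplotype class before conditioning.
    """
    if order < 1 or order > 3:
        raise ValueError("order must be in 1..3")
    if panel.n_samples < min_controls:
        raise ValueError(
            f"control panel has {panel.n_samples} samples; at least "
            f"{min_controls} are required for a stable LD fit"
        )
    called = (panel.codes != MISSING).sum(axis=1)
    n_a2 = (panel.codes == HET).sum(axis=1) + 2 * (panel.codes == HOM2).sum(axis=1)
    mono = (n_a2 == 0) | (n_a2 == 2 * called) | (called == 0)
    if mono.any():
        bad = [str(s) for s in panel.snps["snp_id"][mono][:5]]
        raise ValueError(f"monomorphic SNPs in control panel (QC expected): {bad}")

    chroms: dict[str, ChromLDModel] = {}
    for chrom, sl in panel.chrom_slices().items():
        sub = panel.codes[sl].T  # (n, L)
        meta = panel.snps.iloc[sl]
        L = sub.shape[1]
        probs: list[np.ndarray] = []
        for i in range(L):
            m = min(i, order)
            w = m + 1
            f, _ = window_em(sub[:, i - m : i + 1], tol=tol, max_iter=max_iter)
            counts = f * 2 * panel.n_samples + pseudocount
            # condition the last SNP on the first m alleles of the window
            counts = counts.reshape(2**m, 2)
            probs.append(counts[:, 1] / counts.sum(axis=1))
        chroms[chrom] = ChromLDModel(
            snp_ids=[str(s) for s in meta["snp_id"]],
            order=order,
            probs=probs,
            alleles=[(a1, a2) for a1, a2 in zip(meta["a1"], meta["a2"])],
        )
    return HaplotypeLDModel(chroms=chroms, order=order)


def sample_haplotype(model: HaplotypeLDModel, chrom: str, seed: int) -> np.ndarray:
    """Draw a single haplotype for one chromosome, reproducibly per seed."""
    rng = np.random.default_rng(seed)
    return model.sample(chrom, 1, rng)[0]
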