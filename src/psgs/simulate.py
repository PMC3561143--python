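"""Synthetic study inputs: pedigrees, maps, LD models, controls, and case
genotypes with an embedded shared risk haplotype.

The generator emulates the structure of a dense-array pedigree study at
desk scale: biallelic SNPs with serial LD (an order-1 Markov truth model
whose transition concentration is set by ``ld_strength``), an unrelated
control panel, template extended pedigrees whose case counts and connecting
meioses mirror published extended high-risk pedigrees (5 cases / 17
meioses, 9/20, 10/33 — topologies are approximations, not reconstructions),
and case genotypes produced by gene-dropping in which a designated founder
haplotype segment at a risk locus is forced, by rejection sampling over
transmissions, to be carried IBD by exactly a configured subset of cases
(intra-familial heterogeneity). Missingness and symmetric genotype error
are applied afterwards. Every output is reproducible bit-for-bit from the
master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genedrop import GeneticMapView, drop_genomes
from .genotypes import GenotypeMatrix, HET, HOM1, HOM2, MISSING
from .ldmodel import ChromLDModel, HaplotypeLDModel
from .pedigree import Individual, Pedigree

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "template_pedigree",
    "generate_truth_model",
    "generate_control_panel",
    "generate_case_genotypes",
]


# -- configuration ----------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Knobs of one synthetic dataset (defaults are the desk-scale study
    conditions used throughout the test suite)."""

    pedigree: str = "cousins5"
    n_chrom: int = 1
    snps_per_chrom: int = 2000
    morgans_per_chrom: float = 1.0
    bp_span: int = 100_000_000
    ld_strength: float = 0.5
    n_controls: int = 224
    risk_chrom: int = 0  # index into chromosome list
    risk_index: int | None = None  # SNP index within chromosome; None = centre
    carrier_fraction: float = 0.6
    carrier_ids: tuple[str, ...] | None = None  # overrides the fraction
    missing_rate: float = 0.01
    error_rate: float = 0.001
    seed: int = 0
    max_attempts: int = 2_000_000

    def __post_init__(self) -> None:
        for name in ("ld_strength", "carrier_fraction", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_chrom < 1 or self.snps_per_chrom < 2:
            raise ValueError("need at least 1 chromosome of 2 SNPs")
        if self.morgans_per_chrom < 0:
            raise ValueError("map length must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of one embedded risk haplotype."""

    chrom: str
    risk_index: int  # within-chromosome SNP index
    risk_bp: int
    carrier_ids: tuple[str, ...]
    founder_id: str
    founder_gamete: int
    seed: int
    labels: np.ndarray | None = field(default=None, repr=False)  # (N, 2, L)

    def to_json(self, path) -> None:
        doc = {
            "chrom": self.chrom,
            "risk_index": self.risk_index,
            "risk_bp": self.risk_bp,
            "carrier_ids": list(self.carrier_ids),
            "founder_id": self.founder_id,
            "founder_gamete": self.founder_gamete,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# -- template pedigrees -----------------------------------------------------


def _chain(rows, top_father, top_mother, names, spouse_prefix):
    """Append a descent chain below a couple; returns the last individual."""
    father, mother = top_father, top_mother
    for n, name in enumerate(names):
        rows.append(Individual(name, father, mother, "male", False, False))
        spouse = f"{spouse_prefix}{n}"
        rows.append(Individual(spouse, None, None, "female", False, False))
        father, mother = name, spouse
    return father, mother


def _cases(rows, father, mother, names):
    for name in names:
        rows.append(Individual(name, father, mother, "female", True, True))


def template_pedigree(name: str) -> Pedigree:
    """Built-in pedigree templates.

    ``pair_d2`` / ``pair_d4`` / ``pair_d6``: a single case pair separated by
    2 (half sibs), 4 (first cousins) or 6 (second cousins) meioses through a
    single connecting path. ``sibs``: a full-sib case pair. ``cousins5``
    (and ``cousins5_d6`` / ``_d8`` / ``_d10``): five cousins with every pair
    separated by 4 (6/8/10) meioses. ``ped5_17`` / ``ped9_20`` /
    ``ped10_33``: extended pedigrees with 5/9/10 cases connected by
    17/20/33 meioses.
    """
    rows: list[Individual] = []
    if name == "sibs":
        rows.append(Individual("F", None, None, "male"))
        rows.append(Individual("M", None, None, "female"))
        _cases(rows, "F", "M", ["C1", "C2"])
    elif name == "pair_d2":
        rows.append(Individual("S", None, None, "male"))
        rows.append(Individual("W1", None, None, "female"))
        rows.append(Individual("W2", None, None, "female"))
        _cases(rows, "S", "W1", ["C1"])
        _cases(rows, "S", "W2", ["C2"])
    elif name in ("pair_d4", "pair_d6"):
        depth = 1 if name == "pair_d4" else 2
        rows.append(Individual("G1", None, None, "male"))
        rows.append(Individual("G2", None, None, "female"))
        for side in ("a", "b"):
            f, m = _chain(
                rows, "G1", "G2", [f"{side}{d}" for d in range(depth)], f"{side}s"
            )
            _cases(rows, f, m, [f"C_{side}"])
    elif name in ("cousins5", "cousins5_d6", "cousins5_d8", "cousins5_d10"):
        depth = {"cousins5": 1, "cousins5_d6": 2, "cousins5_d8": 3,
                 "cousins5_d10": 4}[name]
        rows.append(Individual("G1", None, None, "male"))
        rows.append(Individual("G2", None, None, "female"))
        for b in range(5):
            f, m = _chain(
                rows, "G1", "G2", [f"P{b}_{d}" for d in range(depth)], f"P{b}s"
            )
            _cases(rows, f, m, [f"C{b + 1}"])
    elif name == "ped5_17":
        rows.append(Individual("G1", None, None, "male"))
        rows.append(Individual("G2", None, None, "female"))
        f, m = _chain(rows, "G1", "G2", ["A0", "A1"], "As")
        _cases(rows, f, m, ["C1", "C2"])
        for b, (prefix, depth, case) in enumerate(
            [("B", 3, "C3"), ("D", 3, "C4"), ("E", 4, "C5")]
        ):
            f, m = _chain(
                rows, "G1", "G2", [f"{prefix}{d}" for d in range(depth)], f"{prefix}s"
            )
            _cases(rows, f, m, [case])
    elif name == "ped9_20":
        rows.append(Individual("G1", None, None, "male"))
        rows.append(Individual("G2", None, None, "female"))
        f, m = _chain(rows, "G1", "G2", ["P1"], "P1s")
        _cases(rows, f, m, ["C1", "C2"])
        f2, m2 = _chain(rows, f, m, ["Q1"], "Q1s")
        _cases(rows, f2, m2, ["C9"])
        for prefix, cases in [("B", ["C3", "C4"]), ("D", ["C5", "C6"]), ("E", ["C7", "C8"])]:
            f, m = _chain(rows, "G1", "G2", [f"{prefix}{d}" for d in range(3)], f"{prefix}s")
            _cases(rows, f, m, cases)
    elif name == "ped10_33":
        rows.append(Individual("G1", None, None, "male"))
        rows.append(Individual("G2", None, None, "female"))
        for b in range(4):
            f, m = _chain(
                rows, "G1", "G2", [f"B{b}_{d}" for d in range(3)], f"B{b}s"
            )
            _cases(rows, f, m, [f"C{2 * b + 1}", f"C{2 * b + 2}"])
        f, m = _chain(rows, "G1", "G2", [f"E{d}" for d in range(5)], "Es")
        _cases(rows, f, m, ["C9"])
        f, m = _chain(rows, "G1", "G2", [f"F{d}" for d in range(6)], "Fs")
        _cases(rows, f, m, ["C10"])
    else:
        raise ValueError(f"unknown pedigree template {name!r}")
    return Pedigree.from_individuals(rows, family_id=name)


# -- truth model and map ----------------------------------------------------


def generate_truth_model(
    config: SyntheticConfig,
) -> tuple[HaplotypeLDModel, GeneticMapView, pd.DataFrame]:
    """Known-parameter order-1 model plus an evenly spaced genetic map.

    Per SNP a base allele-2 frequency q is drawn uniformly in [0.2, 0.8];
    the transition from the previous allele a is
    (1 - ld_strength) * q + ld_strength * a, so ld_strength 0 is linkage
    equilibrium and 1 near-deterministic serial dependence.
    """
    rng = np.random.default_rng(config.seed)
    lam = config.ld_strength
    chroms: dict[str, ChromLDModel] = {}
    snp_rows = []
    for c in range(config.n_chrom):
        chrom = str(c + 1)
        L = config.snps_per_chrom
        q = rng.uniform(0.2, 0.8, size=L)
        probs = [np.array([q[0]])]
        for i in range(1, L):
            probs.append(
                np.array([(1 - lam) * q[i], (1 - lam) * q[i] + lam])
            )
        snp_ids = [f"c{chrom}_s{i}" for i in range(L)]
        chroms[chrom] = ChromLDModel(
            snp_ids=snp_ids, order=1, probs=probs, alleles=[("A", "B")] * L
        )
        cm = np.linspace(0.0, 100.0 * config.morgans_per_chrom, L)
        bp = np.linspace(1, config.bp_span, L).astype(np.int64)
        snp_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "snp_id": snp_ids,
                    "cm": cm,
                    "bp": bp,
                    "a1": "A",
                    "a2": "B",
                }
            )
        )
    snps = pd.concat(snp_rows, ignore_index=True)
    model = HaplotypeLDModel(chroms=chroms, order=1)
    return model, GeneticMapView.from_snps(snps), snps


# -- control panel ----------------------------------------------------------


def generate_control_panel(
    model: HaplotypeLDModel, snps: pd.DataFrame, n: int, seed: int
) -> GenotypeMatrix:
    """``n`` unrelated control genotypes from independent haplotype pairs."""
    if n < 2:
        raise ValueError("need at least 2 controls")
    rng = np.random.default_rng(seed)
    haps = model.sample_genome(2 * n, rng)
    codes = (haps[0::2] + haps[1::2]).astype(np.int8).T  # (L, n)
    return GenotypeMatrix(
        snps=snps.copy(),
        samples=[f"ctrl_{i + 1}" for i in range(n)],
        codes=codes,
    )


# -- case genotypes with an embedded risk haplotype -------------------------


def _ancestor_founder(ped: Pedigree, carrier_ids) -> str:
    """First founder (in pedigree order) that is an ancestor of every carrier."""
    ancestors: dict[str, set[str]] = {}
    for iid in ped.topological_order():
        ind = ped.individuals[iid]
        anc: set[str] = set()
        for parent in (ind.father, ind.mother):
            if parent is not None:
                anc |= {parent} | ancestors[parent]
        ancestors[iid] = anc
    for f in ped.founders:
        if all(f in ancestors[c] for c in carrier_ids):
            return f
    raise ValueError("no single founder is an ancestor of all designated carriers")


def _apply_noise(
    codes: np.ndarray, missing_rate: float, error_rate: float, rng
) -> np.ndarray:
    out = codes.copy()
    if error_rate > 0:
        flip = rng.random(out.shape) < error_rate
        hom = flip & ((out == HOM1) | (out == HOM2))
        het = flip & (out == HET)
        out[hom] = HET
        out[het] = np.where(rng.random(int(het.sum())) < 0.5, HOM1, HOM2)
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    return out


def _expand_active(state_at: int, at: int, psw: np.ndarray, rng) -> np.ndarray:
    """Fill a meiosis's active-haplotype track (0/1 per SNP) given its state
    at one SNP. The track is a two-state Markov chain with independent
    inter-SNP switch parities, so it extends forward and backward from the
    conditioning point by the same switch probabilities."""
    L = len(psw) + 1
    active = np.empty(L, dtype=np.int8)
    active[at] = state_at
    if at < L - 1:
        sw = rng.random(L - 1 - at) < psw[at:]
        active[at + 1 :] = (state_at + np.cumsum(sw)) % 2
    if at > 0:
        sw = rng.random(at) < psw[:at]
        active[:at] = (state_at + np.cumsum(sw[::-1])[::-1]) % 2
    return active


def _conditional_labels(
    ped: Pedigree,
    gmap: GeneticMapView,
    risk_chrom_idx: int,
    risk_index: int,
    risk_gid: int,
    carriers,
    rng,
    max_attempts: int,
) -> np.ndarray:
    """One transmission draw conditioned on the risk-locus carrier pattern.

    Transmissions are independent across meioses and the carrier pattern
    depends only on each meiosis's state at the risk locus, so rejection
    runs on those scalar states alone; accepted states are then expanded
    into full per-SNP tracks. Equivalent to rejection sampling whole drops,
    at a fraction of the cost.
    """
    order = [i for i in ped.topological_order() if not ped.individuals[i].is_founder]
    gids = {f: (2 * i, 2 * i + 1) for i, f in enumerate(ped.founders)}
    carrier_set = set(carriers)
    chrom_names = gmap.chromosomes()

    # Cases whose carry status shares no meiosis are conditionally
    # independent, so rejection runs per connected component of cases
    # (linked through shared non-founder ancestors), never jointly.
    anc: dict[str, set[str]] = {}
    for iid in ped.topological_order():
        ind = ped.individuals[iid]
        a: set[str] = set() if ind.is_founder else {iid}
        for parent in (ind.father, ind.mother):
            if parent is not None:
                a |= anc.get(parent, set())
        anc[iid] = a
    components: list[list[str]] = []
    for c in ped.case_ids:
        merged = [c]
        rest = []
        for comp in components:
            if any(anc[c] & anc[x] for x in comp):
                merged += comp
            else:
                rest.append(comp)
        components = rest + [merged]

    states: dict[tuple[str, int], int] = {}
    for comp in components:
        inds = sorted(set().union(*(anc[c] for c in comp)), key=order.index)
        meioses = [(iid, p) for iid in inds for p in (0, 1)]
        m_index = {m: i for i, m in enumerate(meioses)}
        found = None
        batch = 10_000
        attempts = 0
        while found is None and attempts < max_attempts:
            b = min(batch, max_attempts - attempts)
            draw = rng.integers(0, 2, size=(b, len(meioses)), dtype=np.int8)
            at_risk: dict[str, tuple[np.ndarray, np.ndarray]] = {
                f: (np.full(b, g0), np.full(b, g1)) for f, (g0, g1) in gids.items()
            }
            for iid in inds:
                ind = ped.individuals[iid]
                pair = []
                for p, parent in enumerate((ind.father, ind.mother)):
                    col = draw[:, m_index[(iid, p)]]
                    f0, f1 = at_risk[parent]
                    pair.append(np.where(col == 0, f0, f1))
                at_risk[iid] = tuple(pair)
            ok = np.ones(b, dtype=bool)
            for c in comp:
                a1, a2 = at_risk[c]
                ok &= ((a1 == risk_gid) | (a2 == risk_gid)) == (c in carrier_set)
            hits = np.flatnonzero(ok)
            attempts += b
            if hits.size:
                found = {m: int(draw[hits[0], i]) for i, m in enumerate(m_index)}
        if found is None:
            raise RuntimeError(
                f"rejection budget exhausted after {max_attempts} transmission "
                f"draws; carrier pattern {tuple(carriers)} may be infeasible for "
                f"pedigree {ped.family_id!r}"
            )
        states.update(found)
    # meioses not constrained by any case component
    for iid in order:
        for p in (0, 1):
            if (iid, p) not in states:
                states[(iid, p)] = int(rng.integers(2))

    # expand accepted risk-locus states into full tracks, chromosome-wise;
    # unconditioned chromosomes use an unconditioned start state
    lab_chunks = []
    for c, chrom in enumerate(chrom_names):
        cm = gmap.cm[chrom]
        L = len(cm)
        psw = 0.5 * (1.0 - np.exp(-2.0 * np.diff(cm) / 100.0))
        at = risk_index if c == risk_chrom_idx else 0
        labs = {
            f: np.array([np.full(L, g0), np.full(L, g1)], dtype=np.int16)
            for f, (g0, g1) in gids.items()
        }
        for iid in order:
            ind = ped.individuals[iid]
            rows = []
            for p, parent in enumerate((ind.father, ind.mother)):
                state = states[(iid, p)] if c == risk_chrom_idx else int(rng.integers(2))
                active = _expand_active(state, at, psw, rng)
                rows.append(labs[parent][active, np.arange(L)])
            labs[iid] = np.array(rows, dtype=np.int16)
        lab_chunks.append(np.stack([labs[cid] for cid in ped.case_ids]))
    return np.concatenate(lab_chunks, axis=2)


def generate_case_genotypes(
    ped: Pedigree,
    model: HaplotypeLDModel,
    gmap: GeneticMapView,
    snps: pd.DataFrame,
    config: SyntheticConfig,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Gene-drop case genotypes carrying a shared risk haplotype.

    Founder haplotypes are sampled once; transmissions are then resampled
    until the designated founder gamete at the risk locus is carried IBD by
    exactly the configured carrier cases, which preserves the natural
    recombination structure around the locus (the conditioned segment-
    length law emerges rather than being imposed). Carrier fraction 0 skips
    the constraint entirely (a pure null draw).
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = gmap.chromosomes()
    chrom = chrom_names[config.risk_chrom]
    L_chrom = gmap.n_snps(chrom)
    risk_index = (
        L_chrom // 2 if config.risk_index is None else int(config.risk_index)
    )
    if not 0 <= risk_index < L_chrom:
        raise ValueError("risk locus outside the map")
    sizes = [gmap.n_snps(c) for c in chrom_names]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    global_risk = int(offsets[config.risk_chrom] + risk_index)
    risk_bp = int(
        snps.loc[snps["chrom"] == chrom, "bp"].to_numpy()[risk_index]
    )

    if config.carrier_ids is not None:
        carriers = tuple(config.carrier_ids)
        unknown = set(carriers) - set(ped.case_ids)
        if unknown:
            raise ValueError(f"carrier ids not among cases: {sorted(unknown)}")
    else:
        n_carriers = int(round(config.carrier_fraction * ped.n_cases))
        if 0 < n_carriers < 2:
            raise ValueError(
                "power scenarios need at least 2 carrier cases; "
                "raise carrier_fraction or set it to 0 for a null draw"
            )
        carriers = tuple(
            str(c)
            for c in sorted(rng.choice(ped.case_ids, size=n_carriers, replace=False))
        )

    founders = ped.founders
    n_f = len(founders)
    fh = model.sample_genome(2 * n_f, rng)  # founder gametes, fixed once

    if not carriers:
        drop = drop_genomes(ped, None, gmap, 1, int(rng.integers(2**31)), trace_ibd=True)
        labels = drop.labels[0]
        founder_id, risk_gid = founders[0], 0
    else:
        founder_id = _ancestor_founder(ped, carriers)
        risk_gid = 2 * founders.index(founder_id)
        labels = _conditional_labels(
            ped, gmap, config.risk_chrom, risk_index, risk_gid, carriers, rng,
            config.max_attempts,
        )

    ar = np.arange(fh.shape[1])
    codes = np.empty((ped.n_cases, fh.shape[1]), dtype=np.int8)
    for c in range(ped.n_cases):
        codes[c] = fh[labels[c, 0], ar] + fh[labels[c, 1], ar]
    codes = _apply_noise(codes, config.missing_rate, config.error_rate, rng)

    genos = GenotypeMatrix(snps=snps.copy(), samples=list(ped.case_ids), codes=codes.T)
    truth = TruthRecord(
        chrom=chrom,
        risk_index=risk_index,
        risk_bp=risk_bp,
        carrier_ids=carriers,
        founder_id=founder_id,
        founder_gamete=risk_gid,
        seed=config.seed,
        labels=labels,
    )
    return genos, truth
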