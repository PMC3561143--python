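"""End-to-end orchestration: QC -> LD fit -> scan -> null -> regions.

The file-based entry points (:func:`run_full_scan`, :func:`run_two_pedigree`)
wrap in-memory drivers (:func:`full_scan`, :func:`two_pedigree_scan`) that
the tests and the CLI share. Outputs are plain text (TSV/BED/JSON) plus a
manifest recording seeds, versions, QC totals and a checksum per file, so a
run is auditable and byte-reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genedrop import GeneticMapView, drop_genomes, mask_to_observed_missing
from .genotypes import GenotypeMatrix, QcThresholds, filter_snps, read_ped_map
from .ldmodel import HaplotypeLDModel, fit_markov_ld
from .pedigree import Pedigree, load_pedigree
from .sharing import locus_sharing_counts
from .significance import (
    NullStatisticStore,
    annotate_regions,
    build_null_store,
    call_regions,
    genomewide_thresholds,
    intersect_regions,
    regions_to_bed,
    regions_to_table,
    statistic_track,
)

__all__ = ["RunConfig", "PipelineError", "full_scan", "run_full_scan",
           "two_pedigree_scan", "run_two_pedigree"]


class PipelineError(RuntimeError):
    """A stage failure with the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        text = f"[{stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)


@dataclass
class RunConfig:
    pedigree_file: str
    case_ped: str
    case_map: str
    control_ped: str
    control_map: str
    out_dir: str
    family: str | None = None
    statistics: tuple[str, ...] = ("psgs", "sgs")
    alpha: float = 0.05
    inner_reps: int = 1000
    threshold_genomes: int = 0  # 0 disables threshold estimation
    seed: int = 1
    ld_order: int = 1
    mask_missing: bool = True
    pooled_null: bool = False
    qc: QcThresholds = field(default_factory=QcThresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        qc = QcThresholds(**doc.pop("qc", {}))
        cfg = cls(**doc, qc=qc)
        for name in ("pedigree_file", "case_ped", "case_map", "control_ped",
                     "control_map"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise PipelineError(
                    "config", f"{name} path does not exist: {p}",
                    "check the paths in the config file",
                )
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- in-memory drivers ------------------------------------------------------


def full_scan(
    ped: Pedigree,
    cases: GenotypeMatrix,
    model: HaplotypeLDModel,
    statistics=("psgs", "sgs"),
    alpha: float = 0.05,
    inner_reps: int = 1000,
    threshold_genomes: int = 0,
    seed: int = 1,
    mask_missing: bool = True,
) -> dict:
    """Observed scan plus empirical significance for one pedigree.

    Returns a dict with per-statistic tracks, p-values, annotated regions,
    and optional thresholds.
    """
    gmap = GeneticMapView.from_snps(cases.snps)
    boundaries = cases.chrom_boundaries()
    codes = cases.subset_samples(ped.case_ids).codes.T  # (N, L)
    weights = ped.pair_weights()
    ss = np.random.SeedSequence(seed)
    out: dict = {"snps": cases.snps, "sharing_counts": locus_sharing_counts(codes)}
    for kind, child in zip(statistics, ss.spawn(len(statistics))):
        inner_seed, outer_seed = (int(s.generate_state(1, dtype='uint64')[0] >> 33) for s in child.spawn(2))
        track = statistic_track(codes, boundaries, kind, weights)
        store = build_null_store(
            ped, model, gmap, inner_reps, inner_seed, kind=kind, weights=weights,
            boundaries=boundaries, observed=cases if mask_missing else None,
        )
        p = store.p_track(track)
        regions = annotate_regions(call_regions(p, cases.snps, alpha), codes)
        thresholds = None
        if threshold_genomes:
            thresholds = genomewide_thresholds(
                ped, model, gmap, store, cases.snps, threshold_genomes, outer_seed,
                kind=kind, weights=weights, alpha=alpha,
                observed=cases if mask_missing else None,
            )
            annotate_regions(regions, codes, thresholds)
        out[kind] = {
            "track": track, "p": p, "regions": regions,
            "store": store, "thresholds": thresholds,
        }
    return out


def two_pedigree_scan(
    peds: tuple[Pedigree, Pedigree],
    cases: tuple[GenotypeMatrix, GenotypeMatrix],
    model: HaplotypeLDModel,
    region_pairs=None,
    regions_a=None,
    regions_b=None,
    alpha: float = 0.05,
    inner_reps: int = 1000,
    seed: int = 1,
    mask_missing: bool = True,
) -> pd.DataFrame:
    """Un-weighted paired-average analysis of two pedigrees' combined cases.

    The null gene-drops both pedigrees independently from the same LD model
    (no genealogical links exist between them), so cross-pedigree sharing
    under the null arises purely from population haplotype frequencies.
    ``region_pairs`` is a list of (RegionCall, RegionCall) to intersect; it
    can be auto-derived from ``regions_a``/``regions_b`` by chromosome.
    """
    ped_a, ped_b = peds
    genos_a, genos_b = cases
    if not genos_a.snps["snp_id"].equals(genos_b.snps["snp_id"]):
        raise PipelineError("two-ped", "pedigree SNP sets differ",
                            "run both pedigrees through the same QC")
    snps = genos_a.snps
    gmap = GeneticMapView.from_snps(snps)
    boundaries = genos_a.chrom_boundaries()
    if region_pairs is None:
        region_pairs = [
            (ra, rb)
            for ra in (regions_a or [])
            for rb in (regions_b or [])
            if ra.chrom == rb.chrom
        ]
    overlaps = []
    for ra, rb in region_pairs:
        inter = intersect_regions(ra, rb)
        if inter is not None:
            overlaps.append(inter)
    codes = np.concatenate(
        [
            genos_a.subset_samples(ped_a.case_ids).codes.T,
            genos_b.subset_samples(ped_b.case_ids).codes.T,
        ],
        axis=0,
    )
    track = statistic_track(codes, boundaries, "two-pedigree")

    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1, dtype='uint64')[0] >> 33) for s in ss.spawn(2))
    drops_a = drop_genomes(ped_a, model, gmap, inner_reps, seed_a)
    drops_b = drop_genomes(ped_b, model, gmap, inner_reps, seed_b)
    codes_a, codes_b = drops_a.codes, drops_b.codes
    if mask_missing:
        codes_a = mask_to_observed_missing(codes_a, genos_a, ped_a.case_ids)
        codes_b = mask_to_observed_missing(codes_b, genos_b, ped_b.case_ids)
    null_vals = np.empty((inner_reps, codes.shape[1]))
    for r in range(inner_reps):
        null_vals[r] = statistic_track(
            np.concatenate([codes_a[r], codes_b[r]], axis=0),
            boundaries, "two-pedigree",
        )
    store = NullStatisticStore(kind="two-pedigree", values=null_vals, seed=seed)
    p = store.p_track(track)

    rows = []
    bps = snps["bp"].to_numpy()
    chroms = snps["chrom"].to_numpy().astype(str)
    s_counts = locus_sharing_counts(codes)
    for region in overlaps:
        loci = np.flatnonzero(
            (chroms == region.chrom) & (bps >= region.start_bp) & (bps <= region.end_bp)
        )
        best_p = float(p[loci].min()) if loci.size else float("nan")
        rows.append(
            {
                "chrom": region.chrom,
                "region": f"{region.start_bp} - {region.end_bp}",
                "length_mb": region.length_mb,
                "two_ped_p": best_p,
                "sharing_mean": float(s_counts[loci].mean()) if loci.size else np.nan,
                "sharing_min": int(s_counts[loci].min()) if loci.size else -1,
                "sharing_max": int(s_counts[loci].max()) if loci.size else -1,
            }
        )
    return pd.DataFrame(rows)


# -- file-based pipeline ----------------------------------------------------


def _stage(stage: str, hint: str = ""):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc), hint) from exc
    return wrap


def run_full_scan(config: RunConfig) -> dict:
    """Run the whole analysis from files and write the result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ped = _stage("pedigree", "check the pedigree file format")(
        load_pedigree, config.pedigree_file, config.family
    )
    cases_raw = _stage("genotypes", "case PED/MAP could not be read")(
        read_ped_map, config.case_ped, config.case_map
    )
    controls_raw = _stage("genotypes", "control PED/MAP could not be read")(
        read_ped_map, config.control_ped, config.control_map
    )
    if list(cases_raw.snps["snp_id"]) != list(controls_raw.snps["snp_id"]):
        raise PipelineError("genotypes", "case and control SNP sets differ",
                            "cases and controls must be typed on the same map")

    combined = GenotypeMatrix(
        snps=cases_raw.snps.copy(),
        samples=cases_raw.samples + controls_raw.samples,
        codes=np.concatenate([cases_raw.codes, controls_raw.codes], axis=1),
    )
    case_ids = [c for c in ped.case_ids if c in cases_raw.samples]
    if len(case_ids) != ped.n_cases:
        missing = set(ped.case_ids) - set(cases_raw.samples)
        raise PipelineError("genotypes", f"cases without genotypes: {sorted(missing)}",
                            "every pedigree case must appear in the case PED")
    filtered, report = _stage("qc")(
        filter_snps, combined, case_ids, controls_raw.samples, config.qc
    )
    report.to_tsv(out_dir / "qc_report.tsv")

    controls = filtered.subset_samples(controls_raw.samples)
    model = _stage("ld-fit", "controls may be too few or monomorphic")(
        fit_markov_ld, controls, config.ld_order
    )
    model.to_json(out_dir / "ld_model.json")

    cases = filtered.subset_samples(case_ids)
    result = _stage("scan")(
        full_scan, ped, cases, model,
        statistics=tuple(config.statistics), alpha=config.alpha,
        inner_reps=config.inner_reps, threshold_genomes=config.threshold_genomes,
        seed=config.seed, mask_missing=config.mask_missing,
    )

    track_tab = pd.DataFrame(
        {
            "chrom": cases.snps["chrom"],
            "snp_id": cases.snps["snp_id"],
            "bp": cases.snps["bp"],
            "S": result["sharing_counts"],
        }
    )
    for kind in config.statistics:
        track_tab[kind] = result[kind]["track"]
        track_tab[f"{kind}_p"] = result[kind]["p"]
    track_path = out_dir / "statistics.tsv"
    track_tab.to_csv(track_path, sep="\t", index=False, float_format="%.6g")

    written = [out_dir / "qc_report.tsv", out_dir / "ld_model.json", track_path]
    thresholds_doc = {}
    for kind in config.statistics:
        regions = result[kind]["regions"]
        bed = out_dir / f"regions_{kind}.bed"
        tsv = out_dir / f"regions_{kind}.tsv"
        regions_to_bed(regions, bed)
        regions_to_table(regions).to_csv(tsv, sep="\t", index=False)
        written += [bed, tsv]
        th = result[kind]["thresholds"]
        if th is not None:
            thresholds_doc[kind] = {
                "suggestive": th.suggestive, "significant": th.significant,
                "n_genomes": th.n_genomes,
            }
    if thresholds_doc:
        tpath = out_dir / "thresholds.json"
        tpath.write_text(json.dumps(thresholds_doc, indent=1))
        written.append(tpath)

    manifest = {
        "psgs_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "qc"},
        "qc": {
            "n_input": report.n_input,
            "n_retained": report.n_retained,
            "removed_by_filter": report.removed_by_filter,
        },
        "files": {p.name: _checksum(p) for p in written},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result["manifest"] = manifest
    return result


def run_two_pedigree(
    config_a: RunConfig, config_b: RunConfig, kind: str = "psgs",
    out_path=None, inner_reps: int = 1000, seed: int = 1,
) -> pd.DataFrame:
    """File-based two-pedigree overlap analysis from two scan configs."""
    res_a = run_full_scan(config_a)
    res_b = run_full_scan(config_b)
    ped_a = load_pedigree(config_a.pedigree_file, config_a.family)
    ped_b = load_pedigree(config_b.pedigree_file, config_b.family)
    # re-read the QC'd matrices from the per-run outputs is unnecessary:
    # both scans ran on the same map, so rebuild from the raw inputs
    cases_a = read_ped_map(config_a.case_ped, config_a.case_map)
    cases_b = read_ped_map(config_b.case_ped, config_b.case_map)
    keep = res_a["snps"]["snp_id"]
    mask_a = cases_a.snps["snp_id"].isin(keep).to_numpy()
    mask_b = cases_b.snps["snp_id"].isin(keep).to_numpy()
    cases_a = cases_a.subset_snps(mask_a)
    cases_b = cases_b.subset_snps(mask_b)
    model = HaplotypeLDModel.from_json(Path(config_a.out_dir) / "ld_model.json")
    table = two_pedigree_scan(
        (ped_a, ped_b), (cases_a, cases_b), model,
        regions_a=res_a[kind]["regions"], regions_b=res_b[kind]["regions"],
        inner_reps=inner_reps, seed=seed,
    )
    if table.empty:
        import warnings

        warnings.warn("no overlapping regions between the two pedigrees")
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
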