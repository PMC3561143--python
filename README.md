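# psgs — weighted pairwise shared genomic segment analysis

`psgs` localizes disease susceptibility loci in **extended high-risk
pedigrees** from dense SNP genotypes. In such pedigrees a rare risk variant
descends from a founder on a haplotype that surviving carrier cases share
identical-by-descent (IBD). IBD probabilities are intractable in large
pedigrees, but identity-by-state (IBS) is trivial to observe: the package
finds *excessively long runs of IBS sharing* among cases and assesses them
empirically against a gene-dropping Monte Carlo null that respects the
pedigree structure, a genetic map, and inter-marker LD.

## The statistics

At SNP *i*, with genotypes coded 11/12/22 and missing treated as
heterozygous, sharing between two cases is impossible only for opposite
homozygotes, and the number of cases sharing is

    S_i = N − min(N11_i, N22_i)        (⌈N/2⌉ ≤ S_i ≤ N)

`R_i(t)` is the number of consecutive SNPs around *i* at which at least *t*
of the *N* cases share; `R_i(N)` is the classic all-share **SGS** run
length, and `R_i^jk(2)` the run length for the case pair (*j*, *k*). The
primary statistic is the meiosis-weighted pairwise mean

    pSGS_i = Σ_{j<k} d_jk · R_i^jk(2) / Σ_{j<k} d_jk

where `d_jk` counts the meioses separating the pair (siblings 2, first
cousins 4, …). Long runs in distant pairs are more surprising — a pair
separated by *d* meioses shares null IBD segments of mean length 1/*d*
Morgans, while the segment around a truly shared disease locus has mean
2/*d* — and the pairwise form keeps power when only a subset of cases
carries any one risk haplotype (intra-familial heterogeneity).

Significance is empirical: founder haplotypes are drawn from an order-k
Markov haplotype model fitted to unrelated controls (so the null carries
realistic LD), segregated through the pedigree with Poisson/Haldane
recombination on the genetic map, and the observed track is compared locus
by locus to the null replicates, p = (1 + #{null ≥ obs})/(1 + n).
Nominal regions are maximal runs of loci with p ≤ 0.05; genomewide
suggestive/significant thresholds are the segment p-values crossed 1.0 /
0.05 times per genome across simulated null genomes, and each region's μ
reports how many equally extreme findings a null genome would yield.

## Worked example

Simulate a study around a deep 5-case cousin pedigree in which only 3 of
the 5 cases carry the embedded risk haplotype, then scan it:

```bash
psgs simulate --pedigree cousins5_d10 --snps 2000 --controls 224 \
      --carrier-fraction 0.6 --seed 11 --out-dir study
# wrote synthetic study to study (carriers: C1, C4, C5)

cat > run.yaml <<EOF
pedigree_file: study/pedigree.fam
case_ped: study/cases.ped
case_map: study/cases.map
control_ped: study/controls.ped
control_map: study/controls.map
out_dir: out
inner_reps: 500
seed: 3
EOF
psgs psgs-scan --config run.yaml
# scan complete; nominal regions: {'psgs': 19, 'sgs': 13}; outputs in out
```

The simulated truth (`study/truth.json`) places the risk haplotype at
bp 50,025,013 with carriers C1, C4, C5. The best locus of the scan
(`out/statistics.tsv`) sits on top of it:

```
 chrom   snp_id       bp  S  psgs   psgs_p  sgs    sgs_p
     1 c1_s1004 50225113  5  54.4 0.001996    4 0.189621
```

The weighted pairwise statistic flags the locus at p ≈ 0.002 while the
all-share SGS run is unremarkable (p ≈ 0.19) — two of the five cases are
non-carriers, which breaks every all-share run but leaves the carrier
pairs' long runs intact. The called region around the best locus
(`out/regions_psgs.tsv`) spans 47,323,662–52,476,238 (5.2 Mb, best
p = 0.002, 3–5 cases sharing) and contains the true risk position.

Other subcommands: `qc` (SNP filters: differential missingness p < 10⁻⁵,
missing rate > 5%, MAF < 1%, exact HWE p < 10⁻⁴), `fit-ld`, `gene-drop`,
`thresholds`, `regions`, `two-ped-scan` (un-weighted paired average across
two pedigrees' combined cases), `simulate`.

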