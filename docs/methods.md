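# Methods

## Model and procedure

The package implements shared genomic segment (SGS) mapping for extended
pedigrees. The data are dense biallelic SNP genotypes for N affected,
genotyped cases of one pedigree plus an unrelated control panel typed on
the same map. The chain of computation is:

1. **SNP QC** — remove SNPs with differential case/control missingness
   (two-sided Fisher exact p < 10⁻⁵), combined missing rate > 5%, control
   minor allele frequency < 1%, or exact-test Hardy–Weinberg p < 10⁻⁴ in
   controls. MAF and HWE use controls only: pedigree cases are relatives
   and violate the independence both quantities assume. The HWE test is the
   exact conditional test (probabilities of all heterozygote counts
   compatible with the observed allele counts, built by recurrence); a
   chi-square variant exists behind a flag for very large panels. Filters
   are evaluated independently on the input, so their order is immaterial.
2. **LD model** — an order-k Markov chain over alleles per chromosome
   (default k = 1), fitted from control genotypes by
   expectation–maximization over the phase ambiguity in sliding windows of
   k+1 SNPs, with a pseudocount of 0.5 per window haplotype class so no
   transition is exactly 0 or 1. EM starts from linkage-equilibrium
   haplotype frequencies and stops when the largest frequency change falls
   below 10⁻⁶ or after 500 iterations; the per-window log-likelihood is
   non-decreasing (tested). This chain replaces a decomposable
   graphical-model LD estimator used in the original analyses of real
   data: the Markov approximation captures the dominant serial LD that
   inflates IBS run lengths — the component that matters for the null —
   while remaining fully specifiable and cheap to sample. This is the
   package's major modelling approximation.
3. **Sharing statistics** — S_i, R_i(t), pairwise run lengths, the
   weighted pSGS mean Σd·R/Σd, the all-share SGS track R_i(N), and the
   un-weighted pairwise mean for cases pooled from two pedigrees (between
   which no meiosis count exists). Missing genotypes become heterozygotes
   only inside the sharing comparison — QC and reporting see true
   missingness. Runs are counted in SNPs and never cross chromosome
   boundaries. A published rendering of the pSGS formula carries a
   corrupted prefactor; any constant multiple cancels in empirical
   p-values, so the weighted mean is used and raw statistic values should
   not be compared across software without checking that convention.
4. **Gene-dropping null** — founders receive haplotypes sampled from the
   LD model; each non-founder receives one gamete per parent with
   crossovers as a Poisson process at 1/Morgan (Haldane, no interference)
   on the sex-averaged map; genotypes are kept only for the cases.
   Replicated drops use the equivalent per-interval switch probability
   ½(1−e^(−2Δ)), which is the same law at SNP resolution and vectorizes
   across replicates. Null genotypes are masked to missing wherever the
   observed case genotype is missing (flag-controlled, default on) so
   observed and null tracks see identical missingness.
5. **Empirical significance** — per-locus p = (1 + #{null ≥ obs})/(1 + n);
   the add-one correction avoids p = 0. The null store is per-locus by
   default (locus-specific LD and map density shape run lengths); a pooled
   genomewide store is available. Nominal regions are maximal runs with
   p ≤ α (default 0.05), reported from the bp of the first to the last
   nominal locus, with length in Mb at one decimal. Genomewide thresholds:
   scan G extra null genomes exactly like observed data, pool every called
   segment's best (minimum) per-locus p, sort ascending, and read the
   value at rank round(rate·G) — rate 1.0 per genome for suggestive,
   0.05 for significant. The same inner null store is reused for all G
   outer genomes (full re-simulation per genome is cluster-scale). μ for an
   observed p is the pooled count of null segment p-values at or below it,
   divided by G.

## Pedigree handling

Pedigrees are directed ancestry graphs; cases are the affected, genotyped
individuals (everyone else is "unknown" and ungenotyped). Individuals must
have both parents recorded or neither, because gene-dropping needs two
founder gametes per non-founder. d_jk is the length of the shortest
undirected parent–child path; with marriage loops the minimum is a
documented assumption, not a published definition. The "N cases connected
by M meioses" summary is computed as the distinct edges in the union of
one canonical shortest path per case pair; the bundled template pedigrees
reproduce the 5/17, 9/20 and 10/33 summaries of published extended
high-risk pedigrees (their exact topologies are not reconstructable, so
the templates are labelled approximations).

## Synthetic data

The generator emulates a desk-scale array study: per SNP a base allele
frequency is drawn uniformly in [0.2, 0.8] and an order-1 truth chain is
built with transition (1−λ)q + λ·a, so `ld_strength` λ = 0 is linkage
equilibrium and λ = 1 near-deterministic LD; the map is uniform. Defaults:
1 chromosome, 2,000 SNPs, 1 Morgan, 100 Mb, λ = 0.5, 224 controls, 1%
missingness, 0.1% symmetric genotype error (hom↔het flips), risk locus at
the centre SNP, carrier fraction 0.6. The 1-Morgan default reflects array
reality: at 550K-array density 2,000 SNPs span well under a Morgan, so
even 0.05 cM/SNP is conservative about LD span per SNP.

Case genotypes under the alternative are produced by conditioning a gene
drop, not by pasting haplotypes: transmissions are drawn conditional on a
designated founder gamete being carried IBD at the risk locus by exactly
the configured carrier subset. Because the carrier pattern depends only on
each meiosis's state at the risk locus, rejection runs on those scalar
states (independently per connected component of cases, which keeps deep
pedigrees feasible) and each accepted meiosis's switch process is then
expanded forward and backward from the risk locus — the two-state chain
has independent interval parities and is reversible, so this is exactly
the conditional distribution. The conditioned-segment law (mean 2/d
Morgans around the risk locus) then emerges rather than being imposed,
and is verified by test.

What the generator does **not** emulate: real marker spacing and allele
spectra, population structure, long-range or block LD beyond order k,
phenotype/penetrance models, sex-specific maps, crossover interference,
and genotype-error correlation. Passing tests therefore demonstrate
correctness and calibration of the machinery under a faithful but
simplified null, not performance on any particular real array.

## Power experiment design

The heterogeneity experiment (3 of 5 cases carry the risk haplotype; the
scan "localizes" if its best — minimum-p — nominal region contains the
risk locus) is sensitive to the pedigree depth, and the choice is a power
statement worth recording. Conditional on a null IBD segment covering a
fixed locus, its length is length-biased with mean 2/d Morgans — exactly
the length of the conditioned risk segment. A single pair therefore
carries *no* length signal at its own sharing loci; the information is in
the *coincidence* of several specified pairs sharing simultaneously, and
the per-pair null probability of sharing at a locus is ≈2^(2−d). With
first cousins (d = 4) that probability is ¼ and coincidences of three
pairs are routine under the null, so single-chromosome localization power
is intrinsically poor; with d = 10 (within the meiotic range of published
extended pedigrees) it is 1/256 and the embedded locus dominates. The
experiment accordingly uses a 5-case pedigree with all pairs at d = 10, a
1-Morgan 2,000-SNP chromosome, and 500 null replicates (the empirical-p
floor of 1/501 resolves ties between candidate regions that a coarser
floor leaves arbitrary). Under these conditions the weighted pairwise scan
localizes the locus in 47/50 seeded runs and the all-share SGS scan in 0 —
the heterogeneity robustness that motivates the pairwise statistic.

## Numerical and design choices

- Genotypes are int8 codes (0/1/2/3 = hom-1/het/hom-2/missing); allele 1
  is the lexicographically smaller label, so coding is reproducible from a
  PED file alone.
- Coordinates are 1-based inclusive internally; BED exports are 0-based
  half-open with score −log10(best p).
- Empirical p-value ties count in favour of the null (≥), making reported
  p conservative under discreteness.
- Segment lengths in cM extend the SNP-run span by half the flanking
  inter-SNP gap on each interior side (unbiased for boundaries uniform
  within a gap); segments touching chromosome ends are flagged censored.
- The Exp(1/d) law is exact only for pairs joined by a single genealogical
  path. Full siblings have two parallel paths and their union sharing
  process has mean segment length ≈ ¾ Morgan, not ½; the d = 2
  simulations therefore use a half-sib pair.
- Thresholds need G ≥ 20 null genomes; a rank beyond the pooled list
  yields an undefined (None) threshold rather than an extrapolation.
- All randomness flows from numpy SeedSequence spawning, so results are
  bit-reproducible per seed and independent of worker count.
- Desk-scale problem sizes used in the test suite (chosen as the package's
  own test conditions): 2,000-replicate segment-law simulations on a
  10-Morgan, 4,001-SNP chromosome; null calibration on a 20-chromosome ×
  75-SNP genome with 999 inner and 500 outer replicates; 50-seed power
  runs with 500 inner replicates.

## Known limitations

- The Markov LD model understates haplotype-block structure; nulls on real
  data with strong block LD may be anti-conservative at block boundaries.
  Fidelity to the original graphical-model null cannot be assessed without
  that software and the original genotypes.
- Genotyping error is injected into observed synthetic data but not into
  null drops (matching the published procedure's silence); at high error
  rates this asymmetry deflates observed run lengths relative to the null.
- Pedigree-specific genomewide thresholds published for real pedigrees
  depend on unpublished genotype data and are context, not reproduction
  targets.
- Only autosomal, sex-averaged inheritance is modelled; no interference,
  no X chromosome, at most two pedigrees combined.
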