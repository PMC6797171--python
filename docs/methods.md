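# Methods

## Differentiation model and estimator

Population differentiation at a biallelic SNP is summarised by F_ST,
estimated per population pair with the two-deme Weir–Cockerham
variance-components estimator θ̂ = a/(a+b+c). With r = 2 demes,
diploid sample sizes n₁, n₂ (missing genotypes excluded, so nᵢ varies
by site), sample frequencies p̂ᵢ and observed heterozygote proportions
hᵢ:

- n̄ = (n₁+n₂)/2, n_c = (2n̄ − (n₁²+n₂²)/(2n̄)),
- p̄ = weighted mean frequency, s² = weighted between-deme variance,
  h̄ = weighted heterozygosity,
- a, b, c are the between-population, within-population-between-
  individual, and within-individual components.

θ̂ is undefined at pooled-monomorphic sites, which are removed first
(`filter_monomorphic`, default mode `pooled`; an `any-pop` mode drops
sites monomorphic in any single population, but that reading would also
discard fixed differences — exactly the most differentiated sites a
scan is meant to find — so it is not the default). Negative θ̂ values
from sampling noise are retained for ranking: clamping to zero would
pile a large tie mass at 0 and distort the percentile cut; a
`clamp=True` flag exists for reporting.

Hudson's estimator,
num = (p̂_A−p̂_B)² − p̂_A(1−p̂_A)/(n_A−1) − p̂_B(1−p̂_B)/(n_B−1) over
den = p̂_A(1−p̂_B)+p̂_B(1−p̂_A) (n here are allele counts), is
implemented as an independent cross-check; the two agree within 0.02 on
balanced Balding–Nichols simulations with ≥50 diploids per deme.

"Mean F_ST over many loci" is always the multilocus ratio-of-sums
combination Σa / Σ(a+b+c) (`multilocus_fst`), the standard multi-locus
estimator. Averaging per-locus ratios instead is biased downward by
low-information loci (we measure ≈0.148 for a planted F of 0.2) and is
not used anywhere.

## pdSNP rule and population tree

Within each pair, the top fraction q (default 0.01) of finite scores is
selected: the threshold is the ⌈qn⌉-th largest score and every score
tied with it is included, making the rule deterministic and
permutation-invariant. Thresholds are per pair, not global. The global
pdSNP set is the union over pairs, each SNP annotated with its
supporting-pair count.

The population distance matrix holds each pair's mean F_ST over its
*own* top-1% set (a union-based mode would mix thresholds across
pairs). UPGMA (average linkage, size-weighted cluster updates) is the
default tree method because mean pairwise divergence is naturally
displayed as a rooted ultrametric dendrogram; ties are broken by merging
the pair containing the lexicographically smallest member label, so the
tree is reproducible. Neighbour joining (scikit-bio) is available for
an additive, unrooted alternative.

## Gene regions

Coordinates are 1-based inclusive internally (VCF/GFF3 convention).
The promoter is the 5,000 bp (configurable) immediately upstream of the
TSS on the gene's strand — for minus-strand genes, coordinates greater
than the TSS — truncated at chromosome edges. Introns are transcript
minus exons; UTRs are the exonic bases up/downstream of the CDS in
transcription order. Multiple transcripts of a gene are merged by
union per label before SNP assignment, because all downstream tallies
are gene-keyed. A SNP overlapping several labels takes one by the
precedence coding > utr5 > utr3 > promoter > intron (configurable; the
choice is logged), then the lexicographically smallest gene id. This
yields disjoint category proportions summing to 1.

pdGene: ≥1 pdSNP in a genic label; enriched pdGene: ≥3 (same for the
potentially-functional pf subset, which enters as an external
snp_id→tag table; pf-pdSNPs are the intersection). Intergenic SNPs
never count toward genes.

## LD pruning

r² is the squared Pearson correlation of unphased diploid dosages over
jointly non-missing samples; zero-variance vectors give r² = 0 (they
cannot constrain pruning). Pruning is greedy left-to-right per
chromosome over a sliding base-pair window (default 1 Mb, ceiling 0.8):
a candidate is kept iff its r² with every kept SNP within the window is
≤ the ceiling. The victim strategy is `first` (keep the earlier SNP) by
default, with a `lower-maf` option that discards the lower-MAF member
of a conflicting pair. The verifiable contract — audited exhaustively
in tests and by `scripts/acceptance.py` — is that the retained set
contains no within-window pair above the ceiling; both strategies
satisfy it.

## Enrichment

Fisher 2×2: two-sided p by the minimum-likelihood definition (sum of
all hypergeometric outcomes with point probability ≤ the observed
one). Tables with total ≤ 300 are evaluated by exact integer
enumeration — all point probabilities share one denominator, so the ≤
comparison is exact integer arithmetic with no floating-point tie
ambiguity — and larger tables fall back to scipy, which implements the
same definition. The reported odds ratio is the sample cross-product
ad/bc (the conventional companion of printed survey ORs), with
Haldane–Anscombe +0.5 on all cells iff any cell is zero. The
"all SNPs vs genome" contrast uses the region nucleotide composition
scaled to the SNP total as its background row
(`scaled_background_counts`); contrast construction is explicit
configuration since a 2×2 can be margined several ways.

Gene-set enrichment: upper-tail hypergeometric
P(X ≥ overlap | universe, set size, query size), BH FDR across sets,
significance at adjusted p < 0.05. The per-chromosome grid runs one
test battery per chromosome's query genes and adjusts within each
chromosome (per-cluster adjustment, as in compareCluster-style
comparisons). Null calibration at universe 20,000 / set 1,000 / query
1,000 gives a raw-p<0.05 rate of ≈0.047 — slightly conservative, as
expected for a discrete test statistic.

## Chromosome architecture

Per-chromosome proportions are within-chromosome ratios (pdSNPs on the
chromosome / all SNPs on the chromosome; pdGenes / genes), the only
reading under which chromosomes are comparable units. Six OLS
regressions are reported: pd and pf-pd SNP proportion vs length, pd and
pf-pd gene proportion vs length, and gene proportions vs gene count,
each with slope, R² and the slope t-test p (n−2 df) at full precision.
A constant response is reported as slope 0, R² 0. Sex-chromosome-style
contigs receive no special treatment; the chromosome list is
configuration. "No effect" in null checks means a slope not
significantly different from zero at α = 0.05.

## Synthetic data

The generator emulates the study conditions the pipeline targets:

- **Frequencies.** Ancestral frequencies uniform on (0.05, 0.95)
  (avoiding monomorphic draws); population frequencies by
  Balding–Nichols Beta draws at divergence F, optionally drifting
  hierarchically along a nested `tree_spec` (one Beta step per branch
  with its own F) to plant group structure. Defaults: 2 populations,
  50 diploids each, F = 0.1 — sizes at which the estimator-recovery
  checks run in seconds.
- **Genotypes.** Binomial(2, p) per sample (Hardy–Weinberg); optional
  missingness rate (default 0).
- **LD.** Blocks of `ld_block_size` consecutive SNPs share one
  frequency draw; haplotype alleles copy a per-block anchor haplotype
  with probability 0.95, giving within-block adjacent r² ≈ 0.8 and
  between-block independence. This is deliberately not a coalescent:
  no recombination maps, mutation model, or realistic decay of LD with
  distance — sufficient to exercise windowed pruning, but passing
  tests say nothing about haplotype-scale realism.
- **Gene models.** 1–5 exon transcripts of 2–10 kb on both strands,
  chromosome chosen proportional to length, exonic span partitioned
  into 5'UTR/CDS/3'UTR in transcription order; genes may overlap, and
  intergenic space always exists at the default density.
- **Gene sets.** Uniform draws, plus one optional planted set whose
  members come preferentially from genes spanning the most divergent
  simulated SNPs.

Everything is driven by one integer seed (numpy `default_rng`),
recorded in the VCF header; fixed seed ⇒ byte-identical output files.

Test problem sizes (20,000 SNPs for estimator recovery, 2,000 SNPs for
pruning audits, 8 chromosomes × 1,500 SNPs for architecture fixtures,
20 replicates for tree recovery) were chosen as the smallest scales at
which the checked effects are statistically unambiguous; they are the
package's own test conditions, not estimates of any full-genome study.

## Known limitations

- Two-deme θ̂ only; no windowed or haplotype F_ST, no admixture or
  significance model for F_ST itself (the scan is a pure percentile
  rule by design).
- Biallelic SNPs only; multi-allelic records are skipped on read;
  indels/SVs unsupported; no phasing.
- The genomic null for region odds ratios assumes uniform SNP
  placement; real mutation-rate heterogeneity is not modelled.
- Disease/pathway ontologies are not bundled: any GMT file serves as
  the term map, and the pf annotation is a user-supplied table, not a
  functional predictor.
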