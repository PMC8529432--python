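# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and containers

All internal coordinates are 0-based half-open; the cytosine-report TSV
dialect (chrom, 1-based pos, strand, methylated count, unmethylated
count, context, trinucleotide) is converted on read/write. Cytosine data
live in pandas DataFrames with columns
`chrom, pos, strand, context, depth, meth`; a simulated cohort keeps one
shared site table plus site × accession count matrices, which makes
population pooling a column sum.

## Methylation calling

The null hypothesis for a site is "unmethylated": every read then reports
methylated with probability equal to the bisulfite non-conversion rate ε,
estimated by pooling all control-sequence cytosines into a single ratio
Σmeth/Σdepth per accession. Pooling (rather than per-site testing of the
control) is appropriate because the control is unmethylated by
construction, and a per-accession ε absorbs library-to-library conversion
differences. The test is the exact one-sided upper binomial tail — the
alternative (methylation) only inflates the methylated-read count — and
FDR control is Benjamini–Hochberg across all tested sites of an accession
jointly over contexts (per-context stratification is available via
`per_context=True`). A site is called methylated by the textbook step-up
rule (reject at q ≤ α). Sites with depth < 4 are excluded; the depth
threshold is read as "retain depth ≥ 4", the looser of the two
formulations in circulation, and is exposed as `min_depth`.

## DMR detection

Population methylation level is the pooled read-count ratio, not the mean
of per-accession ratios: at 15–20× per accession the pooled ratio is far
more stable, especially for CHH where site levels are ~0.03
(`level_mode="means"` switches to site-mean aggregation). Candidate sites
require pooled depth strictly greater than `min_region_coverage` (10) in
*both* populations and a per-site level difference at least the
context-specific Δ; candidates chain into a region while consecutive
candidates are < 300 bp apart, on the same chromosome, and differ in the
same direction. A region with opposing site effects is uninterpretable as
hyper/hypo, hence the sign-consistency break. Retained regions need ≥ 3
sites, region-level |Δ| above threshold, and Fisher's exact p < 0.05 on
the pooled 2×2 table; the region span runs from the first to the last
candidate site (end-exclusive).

`fisher_exact` computes the two-sided p by summing hypergeometric
probabilities not exceeding the observed table's (relative tie tolerance
1 + 1e-7, the same convention scipy uses), vectorized across regions so
that a genome's worth of candidate regions is one array operation. The
test suite checks it against two independent routes: scipy's
implementation on random tables, and a from-scratch log-factorial
enumeration over *all* 2×2 tables with total ≤ 60.

## Annotation conventions

Feature assignment is a partition: promoter > exon > intron > TE >
intergenic, overlap ≥ 1 bp, one class per DMR, so class counts sum to the
DMR count. Promoters are strand-aware 3-kb windows upstream of the TSS;
the TSS of a minus-strand gene is its end coordinate and upstream extends
to larger coordinates. Window densities use non-overlapping tiles (the
final partial tile kept) and count a DMR in the window containing its
start, which conserves totals across windows; an optional step parameter
enables true sliding windows. The DMR-gene definition (body ± 3 kb
overlap ≥ 1 bp) is monotone in the flank size.

## Metagene profiles

Bins are pooled-ratio levels (Σmeth/Σdepth over all (gene, site)
assignments in the expression group); pooling depth-weights the estimate
and keeps CHH bins stable, with a per-gene-mean mode as an option. A
cytosine inside two genes' windows contributes to both genes — each
gene's profile should see its own neighbourhood. Genes shorter than 20 bp
still contribute through fractional body binning. Expression groups use
the six FPKM bands with boundary values assigned to the higher group
(FPKM = 1000 is "high") and "none" meaning FPKM < 0.1; stratification
defaults to the cohort-mean FPKM with a per-accession option.

## Methylation–expression coupling

Promoter windows are context-specific (CG/CHG 0–200 bp, CHH 200–1000 bp
upstream of the TSS, truncated at chromosome edges), and only genes whose
across-accession window levels straddle the context's variability cuts
are analysed. Expression enters as log₂(FPKM + 1): Pearson correlation on
raw FPKM is dominated by the heavy right tail (a raw-scale mode exists).
Per-gene significance defaults to p < 0.01 with ≥ 5 paired observations.
The "expected" counts in the sign-enrichment analysis have no canonical
null; the implemented null permutes the accession labels of the
expression table (one shared permutation per iteration) and recounts
significant correlations by sign, with the empirical p the fraction of
permutations reaching the observed count. With ten accessions there are
10! label permutations, ample for 200–1000 draws.

## Population genetics

Fst is the Weir & Cockerham (1984) estimator with the heterozygosity
terms, summed over a window as Σa / Σ(a+b+c) — the "weighted" form that
vcftools computes; a Hudson-style estimator was considered but W&C is
what the standard tooling reports, and the estimator may legitimately dip
slightly below zero. Sites where either population has < 2 genotyped
individuals are dropped. For Tajima's D, dosages are expanded to 2N
haplotypes under random mating; sites with any missing genotype are
excluded so the haplotype count n in the a₁…e₂ constants is constant, and
windows with S = 0 or n < 4 are NaN-flagged rather than raised. π uses
per-site haplotype counts (missing genotypes drop that accession at that
site) and divides by window length, so monomorphic positions contribute
zero. DSRs take the top 5% of defined window Fst values with ties at the
quantile threshold included; the DSR caller requires ≥ 20 defined windows
to make a 5% quantile meaningful. The DMR-density and popgen stages share
one window grid so the Fst–DMR correlation joins on window identity.

## Synthetic cohort: what it emulates

The generator reproduces the *statistical* structure the analysis
assumes, not sequencing artifacts:

- **Reference and contexts.** A random sequence at GC 0.44 per
  chromosome; cytosines of both strands are extracted with their
  trinucleotide context, so CG/CHG/CHH site proportions and spacings are
  realistic for that base composition. No alignment, M-bias or read-level
  error structure is simulated.
- **Site levels.** Context baselines (CG 0.9, CHG 0.7, CHH 0.03 —
  matching the rank order and rough magnitudes of methylated-site
  fractions in plant WGBS) are shifted by ±Δ inside planted DMRs for one
  randomly chosen population. CG/CHG baselines leave no headroom for a
  +0.4–0.6 shift, so their planted DMRs are hypomethylation events (in
  either population, so hyper and hypo both occur relative to A); CHH
  DMRs are hypermethylation events. Within-population variation is a
  beta jitter reparameterized by (mean, concentration), concentration 50
  (site-level s.d. ≈ 0.04 at level 0.9) — no published
  within-population variance model exists for these cohorts, and the
  beta keeps levels in [0, 1]. Observed counts are Binomial(depth,
  level + (1−level)ε) with depth ~ Poisson(17) (the cohort-scale average
  coverage) and ε = 0.005.
- **Truth DMR spans** run from the first to the last affected context
  cytosine: the bases between sites carry no methylation signal, so this
  is the span against which base-pair sensitivity and precision are
  well-defined.
- **Coupled genes** receive per-accession promoter-window target levels
  spread across (and beyond) the variability-filter band of their
  context, then expression is generated from the *realized*
  (count-derived) window level: log₂(FPKM+1) = 5 + 1.5·(r·z + √(1−r²)ε)
  with z the standardized realized level. Generating from realized rather
  than intended levels means the planted correlation survives binomial
  sampling noise and the recovered r estimates the target directly.
  lncRNA-flagged coupled genes get |r| boosted by 0.05 (capped at 0.99)
  to emulate their stronger coupling. Uncoupled genes draw
  log₂(FPKM+1) means uniformly on [0, 11], spanning all six expression
  groups.
- **Genotypes.** Background SNPs share one ancestral frequency per site
  (uniform on [0.05, 0.95]) between populations; inside divergent
  windows — chosen as tiles of the analysis window grid so DSR scoring
  joins exactly — the two populations' frequencies are independent
  Balding–Nichols draws with F equal to the target Fst, giving
  E[Fst] ≈ target. Genotypes are Binomial(2, p) per accession; no
  linkage is simulated.
- **Genes** are placed on an even grid with ≥ 3.5 kb margins (promoter
  room), lengths 1.2–2.5 kb, 1–3 exons; TEs are uniform random
  intervals. Even spacing means per-window gene counts are constant —
  convenient for conservation checks, but it removes gene-density
  variation, so the gene-density correlation of the annotation stage is
  only exercised against non-uniform inputs in tests.

Consequently, passing recovery tests show the *inference machinery* is
correct and calibrated under the assumed generative model; they do not
certify performance against alignment artifacts, copy-number variation,
non-beta within-population variance or linked selection.

## Determinism and problem sizes

Every stochastic step draws from `numpy.random.Generator` streams spawned
from a single seed (`SeedSequence.spawn`), one child per accession and
per subsystem, so outputs are byte-reproducible end to end; the pipeline
writes all tables with fixed float formatting for that reason. Benchmarks
use a 10-Mb single-chromosome genome at 20× for DMR recovery (200 CG +
100 CHH planted regions), 500 coupled genes across 10 accessions for
correlation recovery, and 2-Mb cohorts with 20 windows for the
integration replicates — sizes at which every recovery metric is
measurable with tight Monte-Carlo error while a full run of the suite
stays in the minutes range on one CPU.

## Known limitations

- The DMR chainer implements the published criteria directly; it is not a
  beta-binomial shrinkage caller, so single-accession outliers are
  handled only through pooling.
- Tajima's D with heavy missingness discards incomplete sites rather than
  adapting n per site.
- The sign-enrichment null permutes whole accessions, which preserves
  per-gene level structure but not inter-gene expression correlation.
- lncRNA identity is an annotation flag; no sequence-level lncRNA
  features are simulated.
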