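# epidiverge

Population-epigenomic divergence analysis for plant cohorts, built around
the comparison of two wild populations (e.g. barley accessions from
adjacent soil types) profiled with whole-genome bisulfite sequencing,
RNA-seq and genome resequencing. The package provides the full analysis
chain as a tested Python library, plus a seeded synthetic-cohort generator
so every stage can be exercised — and its error rates measured — without
any sequencing data.

## What it computes

**Methylation calling.** Each cytosine (contexts CG, CHG, CHH; H = A, C
or T) with read depth ≥ 4 is tested against the bisulfite non-conversion
rate ε estimated from an unmethylated control (the chloroplast genome):
one-sided binomial p = P(X ≥ m | n, ε) for m methylated reads out of n,
with Benjamini–Hochberg FDR control at α = 0.05 per accession.

**DMR detection.** Differentially methylated regions between populations
use pooled read counts per population and the criteria: per-site pooled
coverage > 10 in both populations, ≥ 3 same-direction differential
cytosines with < 300 bp between neighbours, region-level difference
|m̄_A − m̄_B| ≥ 0.4 (CG, CHG) or 0.2 (CHH), and two-sided Fisher's exact
p < 0.05 on the region's pooled 2×2 methylated/unmethylated table. DMRs
are hyper- or hypo-methylated relative to population A.

**Annotation.** DMRs are assigned to promoter (3 kb upstream of TSS),
exon, intron, TE or intergenic classes (in that precedence, one class per
DMR); *DMR-genes* are genes whose body ± 3 kb flanks overlap a DMR; DMR
densities are counted on a fixed window grid.

**Metagene profiles.** Genes are stratified into six FPKM bands
(high > 1000 down to none < 0.1) and methylation is profiled over gene
body ± 2 kb, 20 fragments per section, strand-oriented.

**Methylation–expression coupling.** Per gene and accession, promoter
methylation is pooled over 0–200 bp upstream of the TSS (CG, CHG) or
200–1000 bp (CHH); genes passing context-specific variability filters
(CG < 0.2 and > 0.8 in at least one accession each; CHG 0.2/0.5;
CHH 0.02/0.1) are correlated with log₂(FPKM + 1) across accessions
(Pearson). Sign enrichment of significant correlations is assessed against
an accession-label permutation null, and mRNA vs lncRNA coupling strength
is contrasted by rank-sum on |r|.

**Population genetics.** On the same window grid: Weir & Cockerham (1984)
Fst (window value = Σaᵢ / Σ(aᵢ+bᵢ+cᵢ)), per-population Tajima's D
(D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1))) and nucleotide diversity π
(Σ 2p(1−p)·n/(n−1) per bp). Windows in the top 5% of Fst are
*differential sequence regions* (DSRs); genes inside them are DSR-genes,
compared with DMR-genes by set overlap, and window Fst is correlated with
per-context DMR counts.

**Synthetic cohorts.** `SimConfig`/`generate_cohort` build a 5-vs-5
two-population cohort from a random GC-0.44 reference: beta-jittered site
levels observed through Poisson depth and binomial counts with a
non-conversion error process, planted DMRs, an unmethylated "chloroplast"
control, genes (mRNA/lncRNA) whose promoter methylation is coupled to
expression at a target r, and SNP genotypes with Balding–Nichols
divergence in designated windows — all recorded in a truth manifest that
downstream scoring uses as the oracle.

## Worked example

`examples/` holds one short script per capability. For instance, planting
50 DMRs on a 2-Mb genome and recovering them
(`python examples/03_find_dmrs.py`) prints:

```
CG: 20 DMRs (8 hyper / 12 hypo), mean length 269 bp
CHG: 10 DMRs (4 hyper / 6 hypo), mean length 275 bp
CHH: 20 DMRs (10 hyper / 10 hypo), mean length 293 bp
CG vs planted truth: base-pair sensitivity 1.000, precision 1.000
CHG vs planted truth: base-pair sensitivity 0.997, precision 1.000
CHH vs planted truth: base-pair sensitivity 0.999, precision 1.000
```

Every planted region is rediscovered essentially base-exactly at these
effect sizes (Δ = 0.6/0.5/0.3 at 17× depth): sensitivity is the fraction
of planted bases covered by called DMRs of the same context and
direction, precision the fraction of called bases inside planted regions.
The methylation–expression example (`06`) recovers planted couplings of
r = −0.9 (CG) and +0.9 (CHH) with mean estimated r of −0.925/+0.919 and
permutation p < 0.005, and the integration example (`07`) shows windowed
Fst and DMR counts correlating at r = 0.93 when DMRs are planted inside
divergent windows.

An `epidiverge` command (`simulate`, `call`, `dmr`, `run`, `score`) wraps
the same functions for shell use; `epidiverge run --seed 4 --outdir out/`
executes the whole chain on a simulated cohort and writes a JSON report
with truth scoring.

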