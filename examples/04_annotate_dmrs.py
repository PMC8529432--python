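"""Place DMRs in genomic context: feature classes, DMR-genes, densities.

A DMR is assigned to exactly one class (promoter > exon > intron > TE >
intergenic); a gene is a "DMR-gene" when its body + 3 kb flanks overlap a
DMR; densities are counted in windows shared with the popgen stage.
"""
from epidiverge import (DmrParams, SimConfig, assign_features,
                        density_correlation, dmr_genes, find_all_dmrs,
                        generate_cohort, window_density)

cohort = generate_cohort(SimConfig(genome_spec={"chr1": 2_000_000}, seed=2,
                                   n_planted_dmrs={"CG": 30, "CHG": 0, "CHH": 30},
                                   n_genes=200, n_tes=100))
dmrs = find_all_dmrs(cohort.pooled_table("A"), cohort.pooled_table("B"),
                     DmrParams())
assigned = assign_features(dmrs, cohort.genes, cohort.exons, cohort.tes)
print("feature classes:")
print(assigned["feature"].value_counts().to_string())

dg = dmr_genes(dmrs, cohort.genes)
print(f"\nDMR-genes: union {len(dg['union'])}; "
      + ", ".join(f"{c}: {len(s)}" for c, s in dg["by_context"].items()))

spec = dict(cohort.config.genome_spec)
gene_dens = window_density(cohort.genes, spec, window_bp=100_000)
cg_dens = window_density(dmrs.loc[dmrs["context"] == "CG"], spec, window_bp=100_000)
chh_dens = window_density(dmrs.loc[dmrs["context"] == "CHH"], spec, window_bp=100_000)

corr = density_correlation(cg_dens["count"], gene_dens["count"])
print(f"\nCG-DMR vs gene density: defined={corr['defined']} (the generator "
      "spaces genes evenly, so gene counts have zero variance here)")
corr = density_correlation(cg_dens["count"], chh_dens["count"])
print(f"CG-DMR vs CHH-DMR density: r = {corr['r']:.3f} (p = {corr['p']:.3g})")
# The class counts sum to the DMR total (each DMR is counted once); on real
# data the same correlation machinery relates DMR and gene densities.
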