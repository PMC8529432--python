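"""Planted-truth benchmarks of the pipeline's core claims.

Each function builds a synthetic cohort with a known structure, runs the
relevant stages, and measures recovery or calibration.  They power both the
test suite and the reproduction script; problem sizes are chosen so each
benchmark completes in minutes on one CPU.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .dmr import DmrParams, find_all_dmrs
from .methcall import call_methylation
from .methexpr import (VariabilityFilter, correlate_genes,
                       promoter_window_levels, sign_enrichment)
from .pipeline import score_against_truth
from .popgen import GenotypeTable, dmr_fst_correlation, window_fst
from .annotate import window_density
from .methcall import CONTEXTS
from .simulate import SimConfig, generate_cohort


def caller_calibration(seed: int, *, n_sites: int = 100_000, depth: float = 20.0,
                       nonconversion: float = 0.005, alpha: float = 0.05,
                       n_replicates: int = 20) -> dict:
    """False-call fraction of the binomial caller on unmethylated genomes.

    Each replicate draws ``n_sites`` null cytosines (level = non-conversion
    rate) and reports the fraction called methylated after BH at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_replicates):
        d = rng.poisson(depth, size=n_sites)
        m = rng.binomial(d, nonconversion)
        tab = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n_sites),
                            "strand": "+", "context": "CG", "depth": d, "meth": m})
        calls = call_methylation(tab, nonconversion, alpha=alpha)
        fracs.append(calls["methylated"].mean() if len(calls) else 0.0)
    fracs = np.asarray(fracs, dtype=float)
    return {"mean_false_call_fraction": float(fracs.mean()),
            "max_false_call_fraction": float(fracs.max()),
            "alpha": alpha, "n_sites": n_sites, "n_replicates": n_replicates}


def dmr_recovery(seed: int, *, genome_mb: int = 10, depth: float = 20.0,
                 n_cg: int = 200, n_chh: int = 100,
                 cg_effect: float = 0.6, chh_effect: float = 0.3) -> dict:
    """Base-pair sensitivity/precision of DMR calling on planted truth.

    5-vs-5 cohort on a ``genome_mb``-Mb genome with CG DMRs at effect 0.6
    and CHH DMRs at 0.3, called with the standard thresholds.
    """
    cfg = SimConfig(
        genome_spec={"chr1": genome_mb * 1_000_000},
        depth_mean=depth,
        n_planted_dmrs={"CG": n_cg, "CHG": 0, "CHH": n_chh},
        dmr_effect={"CG": cg_effect, "CHG": 0.5, "CHH": chh_effect},
        n_genes=0, n_tes=0,
        n_coupled_genes={"CG": 0, "CHG": 0, "CHH": 0},
        n_snps=0, n_divergent_windows=0,
        seed=seed)
    cohort = generate_cohort(cfg)
    dmrs = find_all_dmrs(cohort.pooled_table("A"), cohort.pooled_table("B"),
                         DmrParams())
    score = score_against_truth(dmrs, pd.DataFrame(), pd.DataFrame(),
                                cohort.truth)
    score["n_called"] = {c: int((dmrs["context"] == c).sum()) for c in ("CG", "CHH")}
    return score


def correlation_recovery(seed: int, *, n_coupled_cg: int = 250,
                         n_coupled_chh: int = 250, target_r: float = 0.9,
                         n_permutations: int = 500) -> dict:
    """Recovery of planted methylation-expression couplings.

    CG genes coupled at -|target_r|, CHH genes at +|target_r|, across 10
    accessions; reports the mean estimated r per context, the
    sign-enrichment empirical p on the planted data, and a calibration
    check of the same statistic on an uncoupled cohort.
    """
    n_genes = n_coupled_cg + n_coupled_chh + 100
    genome_mb = max(4, int(np.ceil(n_genes * 8_000 / 1e6)))
    base = dict(
        genome_spec={"chr1": genome_mb * 1_000_000},
        depth_mean=20.0, n_genes=n_genes, n_tes=0, frac_lncrna=0.1,
        n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
        n_snps=0, n_divergent_windows=0)
    cfg = SimConfig(**base,
                    n_coupled_genes={"CG": n_coupled_cg, "CHG": 0, "CHH": n_coupled_chh},
                    coupling_r={"CG": -abs(target_r), "CHG": -abs(target_r),
                                "CHH": abs(target_r)},
                    seed=seed)
    cohort = generate_cohort(cfg)
    tables = cohort.accession_tables()
    out: dict = {"contexts": {}}
    for context, sign in (("CG", -1), ("CHH", +1)):
        truth_ids = set(cohort.truth.coupled_genes.loc[
            cohort.truth.coupled_genes["context"] == context, "gene_id"])
        genes_sub = cohort.genes.loc[cohort.genes["gene_id"].isin(truth_ids)]
        levels = promoter_window_levels(tables, genes_sub, context,
                                        genome_spec=dict(cfg.genome_spec))
        corr = correlate_genes(levels, cohort.fpkm, cohort.genes, context)
        en = sign_enrichment(levels, cohort.fpkm, n_permutations=n_permutations,
                             seed=seed + 1)
        out["contexts"][context] = {
            "n_planted": len(truth_ids),
            "n_passing_filter": int(len(corr)),
            "mean_r": float(corr["r"].mean()) if len(corr) else np.nan,
            "target_r": sign * abs(target_r),
            "enrichment_p": en["p_negative"] if sign < 0 else en["p_positive"],
        }
    # calibration on an uncoupled cohort: planted-sign count should sit
    # inside the central 95% of its own permutation null
    null_cfg = SimConfig(**base,
                         n_coupled_genes={"CG": 0, "CHG": 0, "CHH": 0},
                         seed=seed + 7)
    null_cohort = generate_cohort(null_cfg)
    null_tables = null_cohort.accession_tables()
    # analyse a fixed slice of genes with a permissive filter so some pass
    levels = promoter_window_levels(null_tables, null_cohort.genes.iloc[:200], "CG",
                                    genome_spec=dict(null_cfg.genome_spec))
    en = sign_enrichment(levels, null_cohort.fpkm, n_permutations=n_permutations,
                         seed=seed + 8, min_n=5)
    null_neg = np.asarray(en["null_negative"])
    lo, hi = np.quantile(null_neg, [0.025, 0.975])
    out["null_calibration"] = {
        "observed_negative": en["observed_negative"],
        "null_lo": float(lo), "null_hi": float(hi),
        "within_central_95": bool(lo <= en["observed_negative"] <= hi),
    }
    return out


def integration_benchmark(seed: int, *, n_null_replicates: int = 20,
                          n_biased_replicates: int = 3) -> dict:
    """DMR-Fst coupling: positive correlation when DMRs are planted inside
    divergent windows, null-calibrated |r| when planted independently."""
    def one(rep_seed: int, biased: bool) -> dict:
        cfg = SimConfig(
            genome_spec={"chr1": 2_000_000}, depth_mean=12.0,
            n_planted_dmrs={"CG": 60, "CHG": 0, "CHH": 0},
            dmr_effect={"CG": 0.6, "CHG": 0.5, "CHH": 0.3},
            dmr_length_bp={"CG": 200, "CHG": 200, "CHH": 200},
            n_genes=0, n_tes=0,
            n_coupled_genes={"CG": 0, "CHG": 0, "CHH": 0},
            n_snps=4000, n_divergent_windows=5, divergent_fst=0.5,
            window_bp=100_000,
            dmr_divergent_frac=0.8 if biased else 0.0,
            seed=rep_seed)
        cohort = generate_cohort(cfg)
        dmrs = find_all_dmrs(cohort.pooled_table("A"), cohort.pooled_table("B"))
        gt = GenotypeTable(cohort.snp_sites, cohort.dosages, cohort.accessions)
        stats_df = window_fst(gt, cohort.populations, dict(cfg.genome_spec),
                              cfg.window_bp)
        for c in CONTEXTS:
            dens = window_density(dmrs.loc[dmrs["context"] == c],
                                  dict(cfg.genome_spec), cfg.window_bp)
            stats_df[f"dmr_count_{c}"] = dens["count"].to_numpy()
        res = dmr_fst_correlation(stats_df)["CG"]
        res["mean_fst_background"] = float(np.nanmean(
            stats_df.loc[stats_df["dmr_count_CG"] >= 0, "fst"]))
        return res

    biased = [one(seed + i, True) for i in range(n_biased_replicates)]
    nulls = [one(seed + 1000 + i, False) for i in range(n_null_replicates)]
    null_within = [r["p"] > 0.05 for r in nulls if r["defined"]]
    return {
        "biased_r": [r["r"] for r in biased],
        "biased_p": [r["p"] for r in biased],
        "null_fraction_within_bounds": float(np.mean(null_within)),
        "n_null_replicates": len(null_within),
    }


def background_fst(seed: int, *, n_snps: int = 20_000) -> dict:
    """Mean windowed Fst with no planted divergence (should be near zero)."""
    cfg = SimConfig(genome_spec={"chr1": 2_000_000}, n_genes=0, n_tes=0,
                    n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
                    n_coupled_genes={"CG": 0, "CHG": 0, "CHH": 0},
                    n_snps=n_snps, n_divergent_windows=0, window_bp=100_000,
                    seed=seed)
    cohort = generate_cohort(cfg)
    gt = GenotypeTable(cohort.snp_sites, cohort.dosages, cohort.accessions)
    w = window_fst(gt, cohort.populations, dict(cfg.genome_spec), cfg.window_bp)
    return {"mean_fst": float(np.nanmean(w["fst"])), "n_windows": int(len(w))}
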