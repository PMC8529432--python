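"""End-to-end orchestration: simulate/load -> call -> DMR -> annotate ->
metagene -> methylation-expression -> popgen -> report.

All stage outputs are written under the run's output directory in the
formats of the corresponding modules, plus a machine-readable JSON report.
When a truth manifest is available (simulated input) the report carries a
scoring block: planted DMRs are recovered if at least half their bases are
covered by called DMRs of the same context and direction; coupled genes by
a sign-correct significant correlation; divergent windows by DSR membership.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .annotate import assign_features, dmr_genes, window_density
from .dmr import DmrParams, find_all_dmrs, pool_population, summarize_dmrs
from .metagene import metagene_profile, profiles_to_frame, stratify_by_expression
from .methcall import CONTEXTS, call_methylation, context_summary, estimate_error_rate
from .methexpr import (PromoterWindowSpec, VariabilityFilter, biotype_contrast,
                       correlate_genes, promoter_window_levels, sign_enrichment)
from .popgen import (GenotypeTable, call_dsr, dmr_fst_correlation, dsr_genes,
                     overlap_venn, window_pop_stats)
from .simulate import Cohort, SimConfig, TruthManifest, generate_cohort
from .windows import assign_to_windows

log = logging.getLogger("epidiverge")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; loadable from YAML."""
    sim: SimConfig | None = None
    input_dir: str | None = None          # fixture directory written by write_fixtures
    outdir: str = "epidiverge_run"
    dmr_params: DmrParams = field(default_factory=DmrParams)
    promoter_windows: PromoterWindowSpec = field(default_factory=PromoterWindowSpec)
    variability_filter: VariabilityFilter = field(default_factory=VariabilityFilter)
    window_bp: int = 100_000
    alpha: float = 0.05
    min_depth: int = 4
    corr_p_threshold: float = 0.01
    n_permutations: int = 200
    seed: int = 0
    write_calls: bool = False
    write_fixture_files: bool = False
    min_dsr_windows: int = 20

    def validate(self) -> None:
        if self.sim is None and self.input_dir is None:
            raise ValueError("either a SimConfig or an input directory is required")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input directory {self.input_dir} does not exist")
        self.dmr_params.validate()
        self.variability_filter.validate()

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["genome_spec"] = dict(d["sim"]["genome_spec"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("sim"):
            d["sim"] = SimConfig(**d["sim"])
        if d.get("dmr_params"):
            d["dmr_params"] = DmrParams(**d["dmr_params"])
        if d.get("promoter_windows"):
            w = d["promoter_windows"].get("windows", d["promoter_windows"])
            d["promoter_windows"] = PromoterWindowSpec(
                windows={k: tuple(v) for k, v in w.items()})
        if d.get("variability_filter"):
            cu = d["variability_filter"].get("cuts", d["variability_filter"])
            d["variability_filter"] = VariabilityFilter(
                cuts={k: tuple(v) for k, v in cu.items()})
        return cls(**d)


def _load_inputs(config: RunConfig):
    """Cohort-shaped inputs either simulated or read from a fixture directory."""
    if config.sim is not None:
        cohort = generate_cohort(config.sim)
        return (cohort.accession_tables(),
                {a: cohort.control_table(a) for a in cohort.accessions},
                cohort.populations, cohort.genes, cohort.exons, cohort.tes,
                cohort.fpkm,
                GenotypeTable(cohort.snp_sites, cohort.dosages, cohort.accessions),
                dict(cohort.config.genome_spec), cohort.truth, cohort)
    d = Path(config.input_dir)
    populations = eio.read_populations(d / "populations.tsv")
    tables, controls = {}, {}
    for acc in populations:
        tables[acc] = eio.read_cytosine_report(d / f"{acc}.cytosine_report.tsv")
        controls[acc] = eio.read_cytosine_report(d / f"{acc}.control_report.tsv")
    genes, exons = eio.read_gff3(d / "annotation.gff3")
    tes = eio.read_bed(d / "tes.bed")
    fpkm = eio.read_fpkm(d / "fpkm.tsv")
    sites, dosages, samples = eio.read_vcf(d / "genotypes.vcf")
    gt = GenotypeTable(sites, dosages, samples)
    sim_cfg = eio.read_json(d / "sim_config.json") if (d / "sim_config.json").exists() else None
    if sim_cfg:
        genome_spec = {k: int(v) for k, v in sim_cfg["genome_spec"].items()}
    else:
        # fall back to observed extents
        allpos = pd.concat([t[["chrom", "pos"]] for t in tables.values()])
        genome_spec = (allpos.groupby("chrom")["pos"].max() + 3).to_dict()
    truth = None
    if (d / "truth.json").exists():
        truth = TruthManifest.from_dict(eio.read_json(d / "truth.json"))
    return tables, controls, populations, genes, exons, tes, fpkm, gt, genome_spec, truth, None


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "effective_config.yaml")
    log.info("run start: seed=%s outdir=%s dmr=%s", config.seed, outdir, config.dmr_params)

    stage = "load"
    report: dict = {"stages": {}, "parameters": {
        "alpha": config.alpha, "min_depth": config.min_depth,
        "window_bp": config.window_bp, "seed": config.seed}}
    try:
        (tables, controls, populations, genes, exons, tes, fpkm, gt,
         genome_spec, truth, cohort) = _load_inputs(config)
        if config.sim is not None and config.write_fixture_files:
            from .simulate import write_fixtures
            write_fixtures(cohort, outdir / "fixtures")
        report["stages"]["load"] = {
            "n_accessions": len(tables),
            "n_sites": {a: int(len(t)) for a, t in tables.items()},
            "n_genes": int(len(genes)), "n_snps": int(len(gt.sites)),
        }

        stage = "call"
        calls = {}
        summaries = {}
        for acc, tab in tables.items():
            err = estimate_error_rate(controls[acc])
            c = call_methylation(tab, err, alpha=config.alpha, min_depth=config.min_depth)
            calls[acc] = c
            summaries[acc] = {"error_rate": err,
                              "summary": context_summary(c).to_dict(orient="index")}
            if config.write_calls:
                eio.write_calls(c, outdir / f"{acc}.calls.tsv")
        report["stages"]["call"] = summaries

        stage = "dmr"
        pooled = pool_population(tables, populations)
        pops = sorted(pooled)
        dmrs = find_all_dmrs(pooled[pops[0]], pooled[pops[1]], config.dmr_params)
        eio.write_dmr_bed(dmrs, outdir / "dmrs.bed")
        report["stages"]["dmr"] = summarize_dmrs(dmrs)

        stage = "annotate"
        assigned = assign_features(dmrs, genes, exons, tes)
        feat_counts = assigned["feature"].value_counts().to_dict() if len(assigned) else {}
        dg = dmr_genes(dmrs, genes)
        win_density = {c: window_density(dmrs.loc[dmrs["context"] == c], genome_spec,
                                         config.window_bp) for c in CONTEXTS}
        gene_density = window_density(genes, genome_spec, config.window_bp)
        assigned.to_csv(outdir / "dmr_features.tsv", sep="\t", index=False)
        report["stages"]["annotate"] = {
            "feature_counts": {k: int(v) for k, v in feat_counts.items()},
            "n_dmr_genes": {c: len(dg["by_context"][c]) for c in CONTEXTS},
            "n_dmr_genes_union": len(dg["union"]),
        }

        stage = "metagene"
        groups = stratify_by_expression(fpkm)
        profiles = {c: metagene_profile(tables[next(iter(tables))], genes, groups, c)
                    for c in CONTEXTS}
        profiles_to_frame(profiles).to_csv(outdir / "metagene.tsv", sep="\t", index=False)
        report["stages"]["metagene"] = {
            "groups": {g: int((groups == g).sum()) for g in groups.unique()}}

        stage = "methexpr"
        corr_frames = []
        enrich = {}
        for c in CONTEXTS:
            levels = promoter_window_levels(tables, genes, c,
                                            config.promoter_windows, genome_spec)
            cg = correlate_genes(levels, fpkm, genes, c,
                                 filt=config.variability_filter)
            corr_frames.append(cg)
            passing = [g for g in levels.index
                       if g in set(cg["gene_id"])] if len(cg) else []
            en = sign_enrichment(levels.loc[passing], fpkm,
                                 p_threshold=config.corr_p_threshold,
                                 n_permutations=config.n_permutations,
                                 seed=config.seed)
            en.pop("null_negative"), en.pop("null_positive")
            enrich[c] = en
        nonempty = [f for f in corr_frames if len(f)]
        correlations = (pd.concat(nonempty, ignore_index=True) if nonempty
                        else corr_frames[0])
        correlations.to_csv(outdir / "gene_correlations.tsv", sep="\t", index=False,
                            float_format="%.6g")
        report["stages"]["methexpr"] = {
            "n_correlated": int(len(correlations)),
            "sign_enrichment": enrich,
            "biotype_contrast": biotype_contrast(correlations) if len(correlations) else None,
        }

        stage = "popgen"
        stats_df = window_pop_stats(gt, populations, genome_spec, config.window_bp)
        for c in CONTEXTS:
            stats_df[f"dmr_count_{c}"] = win_density[c]["count"].to_numpy()
        stats_df["gene_count"] = gene_density["count"].to_numpy()
        stats_df.to_csv(outdir / "window_stats.tsv", sep="\t", index=False,
                        float_format="%.6g")
        dsrs = call_dsr(stats_df, min_windows=config.min_dsr_windows)
        eio.write_bed(dsrs, outdir / "dsrs.bed")
        dsr_set = dsr_genes(dsrs, genes)
        venn = overlap_venn(dg["union"], dsr_set)
        fst_corr = dmr_fst_correlation(stats_df)
        report["stages"]["popgen"] = {
            "n_windows": int(len(stats_df)),
            "n_dsrs": int(len(dsrs)),
            "n_dsr_genes": len(dsr_set),
            "dmr_gene_dsr_gene_venn": venn,
            "dmr_fst_correlation": fst_corr,
            "mean_fst": float(np.nanmean(stats_df["fst"].to_numpy())),
        }

        if truth is not None:
            report["truth_scoring"] = score_against_truth(
                dmrs, correlations, dsrs, truth,
                corr_p_threshold=config.corr_p_threshold)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    eio.write_json(report, outdir / "report.json")
    return report


def _coverage_by_calls(truth_row, called: pd.DataFrame) -> int:
    """Bases of a planted interval covered by same-context+direction calls."""
    sub = called.loc[(called["chrom"] == truth_row["chrom"])
                     & (called["context"] == truth_row["context"])
                     & (called["direction"] == truth_row["direction"])
                     & (called["end"] > truth_row["start"])
                     & (called["start"] < truth_row["end"])]
    if not len(sub):
        return 0
    covered = np.zeros(truth_row["end"] - truth_row["start"], dtype=bool)
    for _, r in sub.iterrows():
        a = max(r["start"], truth_row["start"]) - truth_row["start"]
        b = min(r["end"], truth_row["end"]) - truth_row["start"]
        covered[a:b] = True
    return int(covered.sum())


def score_against_truth(dmrs: pd.DataFrame, correlations: pd.DataFrame,
                        dsrs: pd.DataFrame, truth: TruthManifest, *,
                        recovery_fraction: float = 0.5,
                        corr_p_threshold: float = 0.01) -> dict:
    """Sensitivity / precision / base-pair Jaccard against planted truth."""
    out: dict = {"dmr": {}, "coupled_genes": {}, "divergent_windows": {}}
    planted = truth.planted_dmrs
    for c in CONTEXTS:
        tr = planted.loc[planted["context"] == c] if len(planted) else planted
        ca = dmrs.loc[dmrs["context"] == c] if len(dmrs) else dmrs
        truth_bp = int((tr["end"] - tr["start"]).sum()) if len(tr) else 0
        called_bp = int((ca["end"] - ca["start"]).sum()) if len(ca) else 0
        covered = 0
        recovered = 0
        for _, t in (tr.iterrows() if len(tr) else ()):
            cov = _coverage_by_calls(t, ca)
            covered += cov
            if cov >= recovery_fraction * (t["end"] - t["start"]):
                recovered += 1
        # covered == bases in the intersection of called and planted spans
        # (planted intervals are disjoint; called regions are disjoint per
        # context/direction), so it also measures called-base precision
        union = truth_bp + called_bp - covered
        out["dmr"][c] = {
            "n_planted": int(len(tr)), "n_called": int(len(ca)),
            "sensitivity_bp": covered / truth_bp if truth_bp else np.nan,
            "precision_bp": covered / called_bp if called_bp else np.nan,
            "jaccard_bp": covered / union if union else np.nan,
            "recovered_fraction": recovered / len(tr) if len(tr) else np.nan,
        }
    coupled = truth.coupled_genes
    if len(coupled):
        sig = correlations.loc[correlations["p"] < corr_p_threshold] if len(correlations) else correlations
        hit = 0
        for _, t in coupled.iterrows():
            m = sig.loc[(sig["gene_id"] == t["gene_id"])
                        & (sig["context"] == t["context"])] if len(sig) else sig
            if len(m) and np.sign(m["r"].iloc[0]) == np.sign(t["target_r"]):
                hit += 1
        out["coupled_genes"] = {"n_planted": int(len(coupled)),
                                "recovered": hit,
                                "sensitivity": hit / len(coupled)}
    div = truth.divergent_windows
    if len(div) and len(dsrs):
        in_dsr = 0
        for _, w in div.iterrows():
            m = dsrs.loc[(dsrs["chrom"] == w["chrom"])
                         & (dsrs["end"] > w["start"]) & (dsrs["start"] < w["end"])]
            if len(m):
                in_dsr += 1
        out["divergent_windows"] = {"n_planted": int(len(div)),
                                    "in_dsr": in_dsr,
                                    "sensitivity": in_dsr / len(div)}
    return out
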