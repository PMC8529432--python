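"""Genomic context of DMRs: feature classes, DMR-genes, densities.

Gene tables are DataFrames with columns ``gene_id, chrom, start, end,
strand, biotype`` (0-based half-open); exon tables carry ``gene_id, start,
end``.  The TSS of a minus-strand gene is its last base (the ``end``
coordinate side) and "upstream" extends to larger coordinates.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .methcall import CONTEXTS
from .windows import assign_to_windows, tile_genome

FEATURE_CLASSES = ("promoter", "exon", "intron", "TE", "intergenic")


def promoter_interval(gene: Mapping, promoter_bp: int = 3000) -> tuple[int, int]:
    """Strand-aware promoter interval (``promoter_bp`` upstream of the TSS)."""
    if gene["strand"] == "+":
        return max(0, int(gene["start"]) - promoter_bp), int(gene["start"])
    return int(gene["end"]), int(gene["end"]) + promoter_bp


def _trees_by_class(genes: pd.DataFrame, exons: pd.DataFrame,
                    tes: pd.DataFrame | None, promoter_bp: int) -> dict:
    trees: dict[str, dict[str, IntervalTree]] = {k: {} for k in ("promoter", "exon", "intron", "TE")}

    def add(cls, chrom, start, end, label):
        if end > start:
            trees[cls].setdefault(chrom, IntervalTree()).addi(start, end, label)

    exon_by_gene = {g: grp for g, grp in exons.groupby("gene_id")} if len(exons) else {}
    for _, g in genes.iterrows():
        if g["end"] <= g["start"]:
            raise ValueError(f"gene {g['gene_id']} has zero or negative length")
        ps, pe = promoter_interval(g, promoter_bp)
        add("promoter", g["chrom"], ps, pe, g["gene_id"])
        ex = exon_by_gene.get(g["gene_id"])
        if ex is None or not len(ex):
            add("exon", g["chrom"], int(g["start"]), int(g["end"]), g["gene_id"])
            continue
        ex = ex.sort_values("start")
        prev_end = int(g["start"])
        for _, e in ex.iterrows():
            add("intron", g["chrom"], prev_end, int(e["start"]), g["gene_id"])
            add("exon", g["chrom"], int(e["start"]), int(e["end"]), g["gene_id"])
            prev_end = int(e["end"])
        add("intron", g["chrom"], prev_end, int(g["end"]), g["gene_id"])
    if tes is not None:
        for _, t in tes.iterrows():
            add("TE", t["chrom"], int(t["start"]), int(t["end"]), t.get("te_id", "TE"))
    return trees


def assign_features(dmrs: pd.DataFrame, genes: pd.DataFrame, exons: pd.DataFrame,
                    tes: pd.DataFrame | None = None,
                    promoter_bp: int = 3000) -> pd.DataFrame:
    """Assign each DMR to exactly one feature class.

    Overlap of >= 1 bp counts; a DMR touching several classes is resolved by
    the precedence promoter > exon > intron > TE > intergenic, so the class
    counts partition the DMR set.
    """
    trees = _trees_by_class(genes, exons, tes, promoter_bp)
    feats, labels = [], []
    for _, d in dmrs.iterrows():
        hit_class, hit_label = "intergenic", ""
        for cls in ("promoter", "exon", "intron", "TE"):
            t = trees[cls].get(d["chrom"])
            ov = t.overlap(d["start"], d["end"]) if t is not None else None
            if ov:
                hit_class = cls
                hit_label = sorted(iv.data for iv in ov)[0]
                break
        feats.append(hit_class)
        labels.append(hit_label)
    out = dmrs.copy()
    out["feature"] = feats
    out["feature_id"] = labels
    return out


def dmr_genes(dmrs: pd.DataFrame, genes: pd.DataFrame,
              flank_bp: int = 3000) -> dict:
    """DMR-genes: genes whose body + ``flank_bp`` flanks overlap a DMR.

    Returns per-context gene-id sets, their union, and for each context the
    split into genes hit in the promoter (strand-aware ``flank_bp`` upstream)
    versus in the gene body.
    """
    by_ctx: dict[str, set] = {c: set() for c in CONTEXTS}
    promoter_hit: dict[str, set] = {c: set() for c in CONTEXTS}
    body_hit: dict[str, set] = {c: set() for c in CONTEXTS}

    trees: dict[str, IntervalTree] = {}
    for c in CONTEXTS:
        sub = dmrs.loc[dmrs["context"] == c] if len(dmrs) else dmrs
        for _, d in (sub.iterrows() if len(sub) else ()):
            trees.setdefault((c, d["chrom"]), IntervalTree()).addi(d["start"], d["end"])

    for _, g in genes.iterrows():
        lo = max(0, int(g["start"]) - flank_bp)
        hi = int(g["end"]) + flank_bp
        ps, pe = promoter_interval(g, flank_bp)
        for c in CONTEXTS:
            t = trees.get((c, g["chrom"]))
            if t is None:
                continue
            if t.overlap(lo, hi):
                by_ctx[c].add(g["gene_id"])
            if t.overlap(ps, pe):
                promoter_hit[c].add(g["gene_id"])
            if t.overlap(int(g["start"]), int(g["end"])):
                body_hit[c].add(g["gene_id"])
    union = set().union(*by_ctx.values())
    return {"by_context": by_ctx, "union": union,
            "promoter": promoter_hit, "gene_body": body_hit}


def window_density(items: pd.DataFrame, genome_spec: Mapping[str, int],
                   window_bp: int = 1_000_000) -> pd.DataFrame:
    """Count intervals per tiling window; an item belongs to the window
    containing its start, so per-chromosome counts sum to the item count."""
    win = tile_genome(genome_spec, window_bp)
    counts = np.zeros(len(win), dtype=np.int64)
    if len(items):
        idx = assign_to_windows(items["chrom"].to_numpy(),
                                items["start"].to_numpy(dtype=np.int64), win)
        ok = idx >= 0
        np.add.at(counts, idx[ok], 1)
    out = win.copy()
    out["count"] = counts
    return out


def tss_relative_distribution(dmrs: pd.DataFrame, genes: pd.DataFrame,
                              upstream_bp: int = 3000, n_body_bins: int = 20,
                              upstream_bin_bp: int = 100) -> dict:
    """Histogram of DMR midpoints relative to genes, per context.

    A midpoint falling in a gene's promoter contributes to the upstream
    section (100-bp bins of strand-oriented distance from the TSS); one
    inside a gene body contributes to the fractional body-position section.
    Each section is normalized to sum 1 per context (NaN when empty).
    """
    n_up = upstream_bp // upstream_bin_bp
    out = {c: {"upstream": np.zeros(n_up), "body": np.zeros(n_body_bins)}
           for c in CONTEXTS}
    gene_tree: dict[str, IntervalTree] = {}
    prom_tree: dict[str, IntervalTree] = {}
    for i, g in genes.iterrows():
        gene_tree.setdefault(g["chrom"], IntervalTree()).addi(int(g["start"]), int(g["end"]), i)
        ps, pe = promoter_interval(g, upstream_bp)
        prom_tree.setdefault(g["chrom"], IntervalTree()).addi(ps, pe, i)
    for _, d in (dmrs.iterrows() if len(dmrs) else ()):
        mid = (int(d["start"]) + int(d["end"])) // 2
        c = d["context"]
        t = prom_tree.get(d["chrom"])
        for iv in (t.at(mid) if t is not None else ()):
            g = genes.loc[iv.data]
            dist = (g["start"] - mid) if g["strand"] == "+" else (mid - g["end"] + 1)
            b = int(np.clip((dist - 1) // upstream_bin_bp, 0, n_up - 1))
            out[c]["upstream"][b] += 1
        t = gene_tree.get(d["chrom"])
        for iv in (t.at(mid) if t is not None else ()):
            g = genes.loc[iv.data]
            frac = (mid - g["start"]) / (g["end"] - g["start"])
            if g["strand"] == "-":
                frac = 1.0 - frac
            out[c]["body"][int(np.clip(frac * n_body_bins, 0, n_body_bins - 1))] += 1
    for c in CONTEXTS:
        for sec in ("upstream", "body"):
            tot = out[c][sec].sum()
            out[c][sec] = out[c][sec] / tot if tot > 0 else np.full_like(out[c][sec], np.nan)
    return out


def density_correlation(x: Iterable[float], y: Iterable[float]) -> dict:
    """Pearson r (with two-sided t-test p) between two per-window count
    vectors; zero variance in either yields an undefined-flagged result."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired windows")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "p": np.nan, "n": len(x), "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x), "defined": True}
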