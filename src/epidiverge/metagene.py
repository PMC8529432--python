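"""Expression-stratified metagene methylation profiles.

Genes are grouped by FPKM into six bands (high > 1000, medium high
100-1000, medium 10-100, medium low 1-10, low 0.1-1, none < 0.1) and the
methylation level of each context is profiled over the gene body plus 2 kb
flanks, each section split into 20 fragments and oriented 5'->3' on the
gene's strand (bins 0-19 upstream, 20-39 body, 40-59 downstream).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

EXPRESSION_LABELS = ("high", "medium high", "medium", "medium low", "low", "none")
EXPRESSION_BREAKPOINTS = (1000.0, 100.0, 10.0, 1.0, 0.1)


def stratify_by_expression(fpkm: pd.DataFrame | pd.Series,
                           accession: str | None = None) -> pd.Series:
    """Map each gene to its expression group.

    ``fpkm`` is a gene x accession table (or a per-gene Series); pass an
    accession name to stratify on that accession, or ``None`` for the mean
    over accessions.  Boundary values go to the higher group (FPKM = 1000 is
    "high"); "none" means FPKM < 0.1.
    """
    if isinstance(fpkm, pd.DataFrame):
        values = fpkm[accession] if accession is not None else fpkm.mean(axis=1)
    else:
        values = fpkm
    v = values.to_numpy(dtype=float)
    if (v < 0).any():
        bad = values.index[np.argmax(v < 0)]
        raise ValueError(f"negative FPKM for gene {bad!r}")
    idx = np.searchsorted(-np.asarray(EXPRESSION_BREAKPOINTS), -v, side="left")
    return pd.Series([EXPRESSION_LABELS[i] for i in idx], index=values.index)


@dataclass
class MetageneProfile:
    context: str
    group: str
    bins: np.ndarray          # 3 * bins_per_section pooled levels, NaN if no data
    n_genes: int


def _bin_positions(pos: np.ndarray, gene: Mapping, flank_bp: int,
                   nb: int) -> np.ndarray:
    """Oriented bin index (0 .. 3*nb-1) for positions in the gene's window."""
    start, end = int(gene["start"]), int(gene["end"])
    length = end - start
    rel = np.empty(len(pos), dtype=np.int64)
    up = pos < start
    body = (pos >= start) & (pos < end)
    down = pos >= end
    rel[up] = np.clip((pos[up] - (start - flank_bp)) * nb // flank_bp, 0, nb - 1)
    rel[body] = nb + np.clip(((pos[body] - start) * nb) // length, 0, nb - 1)
    rel[down] = 2 * nb + np.clip((pos[down] - end) * nb // flank_bp, 0, nb - 1)
    if gene["strand"] == "-":
        rel = 3 * nb - 1 - rel
    return rel


def metagene_profile(sites: pd.DataFrame, genes: pd.DataFrame,
                     groups: pd.Series, context: str, *,
                     flank_bp: int = 2000, bins_per_section: int = 20,
                     mode: str = "pooled") -> dict[str, MetageneProfile]:
    """Metagene profile per expression group for one context.

    ``sites`` is a cytosine table with depth and meth counts.  Bin level is
    the pooled ratio over all (gene, site) assignments in the group
    (``mode='pooled'``); ``mode='gene_mean'`` averages per-gene bin levels
    instead.  A cytosine inside two genes' windows contributes to both.
    Short genes contribute through fractional body binning.
    """
    nb = bins_per_section
    sub = sites.loc[sites["context"] == context]
    by_chrom = {c: g.sort_values("pos") for c, g in sub.groupby("chrom", observed=True)}
    arrays = {c: (g["pos"].to_numpy(dtype=np.int64),
                  g["depth"].to_numpy(dtype=np.float64),
                  g["meth"].to_numpy(dtype=np.float64)) for c, g in by_chrom.items()}

    acc: dict[str, list] = {}
    for label in groups.unique():
        acc[label] = [np.zeros(3 * nb), np.zeros(3 * nb), 0,
                      np.zeros(3 * nb), np.zeros(3 * nb)]  # depth, meth, n, gm_sum, gm_n
    for _, gene in genes.iterrows():
        label = groups.get(gene["gene_id"])
        if label is None or label not in acc:
            continue
        entry = acc[label]
        entry[2] += 1
        tup = arrays.get(gene["chrom"])
        if tup is None:
            continue
        pos, depth, meth = tup
        lo = np.searchsorted(pos, int(gene["start"]) - flank_bp, side="left")
        hi = np.searchsorted(pos, int(gene["end"]) + flank_bp, side="left")
        if hi <= lo:
            continue
        b = _bin_positions(pos[lo:hi], gene, flank_bp, nb)
        np.add.at(entry[0], b, depth[lo:hi])
        np.add.at(entry[1], b, meth[lo:hi])
        if mode == "gene_mean":
            gd = np.zeros(3 * nb)
            gm = np.zeros(3 * nb)
            np.add.at(gd, b, depth[lo:hi])
            np.add.at(gm, b, meth[lo:hi])
            has = gd > 0
            entry[3][has] += gm[has] / gd[has]
            entry[4][has] += 1

    out = {}
    for label, (d, m, n, gms, gmn) in acc.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            if mode == "pooled":
                bins = np.where(d > 0, m / np.where(d > 0, d, 1), np.nan)
            elif mode == "gene_mean":
                bins = np.where(gmn > 0, gms / np.where(gmn > 0, gmn, 1), np.nan)
            else:
                raise ValueError(f"unknown mode {mode!r}")
        out[label] = MetageneProfile(context=context, group=label, bins=bins, n_genes=n)
    return out


def profiles_to_frame(profiles: Mapping[str, Mapping[str, MetageneProfile]]) -> pd.DataFrame:
    """Flatten {context: {group: profile}} into a long DataFrame."""
    rows = []
    for context, by_group in profiles.items():
        for group, prof in by_group.items():
            for i, v in enumerate(prof.bins):
                rows.append((context, group, i, v, prof.n_genes))
    return pd.DataFrame(rows, columns=["context", "group", "bin", "level", "n_genes"])
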