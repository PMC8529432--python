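"""Per-gene coupling of promoter methylation and expression.

For every gene the methylation level of a context-specific promoter window
(CG and CHG: 0-200 bp upstream of the TSS; CHH: 200-1000 bp) is pooled per
accession and correlated with expression across accessions.  Only genes
whose window level varies enough across accessions are analysed (CG: below
0.2 and above 0.8 in at least one accession each; CHG: 0.2/0.5; CHH:
0.02/0.1).  Expression enters as log2(FPKM + 1) by default.

The sign-enrichment analysis asks whether significant negative (CG, CHG)
or positive (CHH) correlations are more common than expected under a null
in which accession labels of the expression table are permuted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .methcall import CONTEXTS


@dataclass
class PromoterWindowSpec:
    """Strand-oriented promoter windows, as bp upstream of the TSS.

    A window (a, b) covers upstream offsets a < d <= b; on the plus strand
    these are the positions [tss - b, tss - a), truncated at chromosome
    edges.
    """
    windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"CG": (0, 200), "CHG": (0, 200), "CHH": (200, 1000)})

    def interval(self, gene: Mapping, context: str,
                 chrom_length: int | None = None) -> tuple[int, int]:
        a, b = self.windows[context]
        if gene["strand"] == "+":
            lo, hi = int(gene["start"]) - b, int(gene["start"]) - a
        else:
            lo, hi = int(gene["end"]) + a, int(gene["end"]) + b
        lo = max(0, lo)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi


@dataclass
class VariabilityFilter:
    """Across-accession level cuts a gene must straddle to be analysed."""
    cuts: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"CG": (0.2, 0.8), "CHG": (0.2, 0.5), "CHH": (0.02, 0.1)})

    def validate(self) -> None:
        for c, (lo, hi) in self.cuts.items():
            if not lo < hi:
                raise ValueError(f"filter cuts for {c} must satisfy low < high")


@dataclass
class GeneCorrelation:
    gene_id: str
    context: str
    r: float
    p: float
    n: int
    biotype: str = "mRNA"
    defined: bool = True
    reason: str = ""


def promoter_window_level(sites: pd.DataFrame, gene: Mapping, context: str,
                          spec: PromoterWindowSpec | None = None,
                          chrom_length: int | None = None) -> float:
    """Pooled level over one accession's context sites in the gene's window.

    Returns NaN (missing) when no covered site falls in the window.
    """
    spec = spec or PromoterWindowSpec()
    lo, hi = spec.interval(gene, context, chrom_length)
    sub = sites.loc[(sites["chrom"] == gene["chrom"]) & (sites["context"] == context)
                    & (sites["pos"] >= lo) & (sites["pos"] < hi)]
    depth = sub["depth"].sum()
    if depth <= 0:
        return np.nan
    return float(sub["meth"].sum() / depth)


def promoter_window_levels(tables: Mapping[str, pd.DataFrame], genes: pd.DataFrame,
                           context: str, spec: PromoterWindowSpec | None = None,
                           genome_spec: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Gene x accession matrix of pooled promoter-window levels."""
    spec = spec or PromoterWindowSpec()
    accs = list(tables)
    arrays = {}
    for acc, tab in tables.items():
        sub = tab.loc[tab["context"] == context]
        arrays[acc] = {c: (g["pos"].to_numpy(dtype=np.int64),
                           g["depth"].to_numpy(dtype=np.float64),
                           g["meth"].to_numpy(dtype=np.float64))
                       for c, g in sub.groupby("chrom", observed=True)}
    out = np.full((len(genes), len(accs)), np.nan)
    for i, (_, gene) in enumerate(genes.iterrows()):
        clen = genome_spec.get(gene["chrom"]) if genome_spec else None
        lo, hi = spec.interval(gene, context, clen)
        for j, acc in enumerate(accs):
            tup = arrays[acc].get(gene["chrom"])
            if tup is None:
                continue
            pos, depth, meth = tup
            a = np.searchsorted(pos, lo, side="left")
            b = np.searchsorted(pos, hi, side="left")
            d = depth[a:b].sum()
            if d > 0:
                out[i, j] = meth[a:b].sum() / d
    return pd.DataFrame(out, index=genes["gene_id"].to_numpy(), columns=accs)


def passes_variability_filter(levels, context: str,
                              filt: VariabilityFilter | None = None) -> bool:
    """True iff some accession is below the low cut and some above the high."""
    filt = filt or VariabilityFilter()
    lo, hi = filt.cuts[context]
    v = np.asarray(pd.Series(levels).dropna(), dtype=float)
    if len(v) < 2:
        return False
    return bool(v.min() < lo and v.max() > hi)


def correlate_gene(levels, fpkm, *, min_n: int = 5, log_transform: bool = True,
                   gene_id: str = "", context: str = "",
                   biotype: str = "mRNA") -> GeneCorrelation:
    """Pearson correlation of promoter level vs log2(FPKM + 1) across accessions."""
    x = np.asarray(pd.Series(levels), dtype=float)
    y = np.asarray(pd.Series(fpkm), dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if log_transform:
        y = np.log2(y + 1.0)
    if len(x) < min_n:
        return GeneCorrelation(gene_id, context, np.nan, np.nan, len(x), biotype,
                               defined=False, reason=f"fewer than {min_n} paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GeneCorrelation(gene_id, context, np.nan, np.nan, len(x), biotype,
                               defined=False, reason="zero variance")
    r, p = stats.pearsonr(x, y)
    if not np.isfinite(r):
        return GeneCorrelation(gene_id, context, np.nan, np.nan, len(x), biotype,
                               defined=False, reason="zero variance")
    return GeneCorrelation(gene_id, context, float(r), float(p), len(x), biotype)


def correlate_genes(levels: pd.DataFrame, fpkm: pd.DataFrame, genes: pd.DataFrame,
                    context: str, *, filt: VariabilityFilter | None = None,
                    min_n: int = 5, log_transform: bool = True) -> pd.DataFrame:
    """Filter + correlate every gene; returns one row per analysed gene."""
    filt = filt or VariabilityFilter()
    biotype = dict(zip(genes["gene_id"], genes["biotype"]))
    rows = []
    fpkm = fpkm.loc[:, levels.columns]
    for gid in levels.index:
        lv = levels.loc[gid]
        if not passes_variability_filter(lv, context, filt):
            continue
        gc = correlate_gene(lv, fpkm.loc[gid], min_n=min_n, log_transform=log_transform,
                            gene_id=gid, context=context, biotype=biotype.get(gid, "mRNA"))
        if gc.defined:
            rows.append((gc.gene_id, gc.context, gc.r, gc.p, gc.n, gc.biotype))
    return pd.DataFrame(rows, columns=["gene_id", "context", "r", "p", "n", "biotype"])


def _masked_rowwise_pearson(X: np.ndarray, Y: np.ndarray):
    """Row-wise Pearson r and two-sided t-test p, ignoring NaNs in X.

    X and Y are genes x accessions; NaN cells of X drop the pair in that row.
    Rows with < 3 pairs or zero variance yield NaN.
    """
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    Yz = np.where(mask, Y, 0.0)
    n = mask.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = Xz.sum(axis=1)
        sy = Yz.sum(axis=1)
        sxx = (Xz * Xz).sum(axis=1)
        syy = (Yz * Yz).sum(axis=1)
        sxy = (Xz * Yz).sum(axis=1)
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
        r = np.where((n >= 3) & (vx > 0) & (vy > 0), np.clip(r, -1.0, 1.0), np.nan)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    return r, np.where(np.isnan(r), np.nan, p)


def sign_enrichment(levels: pd.DataFrame, fpkm: pd.DataFrame, *,
                    p_threshold: float = 0.01, n_permutations: int = 1000,
                    seed: int = 0, min_n: int = 5,
                    log_transform: bool = True) -> dict:
    """Observed vs permutation-expected counts of significant correlations by sign.

    The null permutes the accession labels of the expression table (one
    shared permutation per iteration) and recounts significant positive and
    negative correlations.  ``p_positive`` / ``p_negative`` are the fractions
    of permutations whose count reaches the observed one.
    """
    if len(levels) == 0:
        return {"n_genes": 0, "observed_negative": 0, "observed_positive": 0,
                "expected_negative": np.nan, "expected_positive": np.nan,
                "p_negative": np.nan, "p_positive": np.nan,
                "null_negative": [], "null_positive": []}
    X = levels.to_numpy(dtype=float)
    Y = fpkm.loc[levels.index, levels.columns].to_numpy(dtype=float)
    if log_transform:
        Y = np.log2(Y + 1.0)
    enough = (~np.isnan(X)).sum(axis=1) >= min_n
    X, Y = X[enough], Y[enough]

    def counts(Yp):
        r, p = _masked_rowwise_pearson(X, Yp)
        sig = p < p_threshold
        return int((sig & (r < 0)).sum()), int((sig & (r > 0)).sum())

    obs_neg, obs_pos = counts(Y)
    rng = np.random.default_rng(seed)
    null_neg = np.empty(n_permutations, dtype=np.int64)
    null_pos = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        perm = rng.permutation(Y.shape[1])
        null_neg[i], null_pos[i] = counts(Y[:, perm])
    return {
        "n_genes": int(X.shape[0]),
        "observed_negative": obs_neg, "observed_positive": obs_pos,
        "expected_negative": float(null_neg.mean()), "expected_positive": float(null_pos.mean()),
        "p_negative": float((null_neg >= obs_neg).mean()),
        "p_positive": float((null_pos >= obs_pos).mean()),
        "null_negative": null_neg.tolist(), "null_positive": null_pos.tolist(),
    }


def biotype_contrast(correlations: pd.DataFrame) -> dict:
    """Compare |r| distributions between mRNA and lncRNA genes.

    Returns per-biotype mean/median |r| and a Mann-Whitney rank-sum
    comparison; flagged partial when a biotype is absent and underpowered
    when either side has a single gene.
    """
    out: dict = {"by_biotype": {}, "flags": []}
    groups = {}
    for bt in ("mRNA", "lncRNA"):
        sub = correlations.loc[correlations["biotype"] == bt, "r"].abs().dropna()
        groups[bt] = sub.to_numpy()
        out["by_biotype"][bt] = {
            "n": int(len(sub)),
            "mean_abs_r": float(sub.mean()) if len(sub) else np.nan,
            "median_abs_r": float(sub.median()) if len(sub) else np.nan,
        }
    if min(len(groups["mRNA"]), len(groups["lncRNA"])) == 0:
        out["flags"].append("partial: a biotype is absent")
        out["rank_sum"] = {"stat": np.nan, "p": np.nan}
        return out
    if min(len(groups["mRNA"]), len(groups["lncRNA"])) < 2:
        out["flags"].append("underpowered: a biotype has a single gene")
    stat, p = stats.mannwhitneyu(groups["lncRNA"], groups["mRNA"], alternative="two-sided")
    out["rank_sum"] = {"stat": float(stat), "p": float(p)}
    return out
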