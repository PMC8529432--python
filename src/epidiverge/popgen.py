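"""Windowed population-genetic statistics and their integration with DMRs.

Genotypes are biallelic SNP dosages (0/1/2 alternate-allele copies per
diploid accession, -1 for missing).  Between-population divergence is the
Weir & Cockerham (1984) Fst estimator, with the window value formed as the
ratio of summed per-site variance components (the "weighted" form computed
by vcftools).  Within-population statistics are nucleotide diversity pi and
Tajima's D on the same window grid.  Windows in the top 5% of Fst are
differential sequence regions (DSRs); genes overlapping them are DSR-genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .methcall import CONTEXTS
from .windows import assign_to_windows, tile_genome


@dataclass
class GenotypeTable:
    """Biallelic SNP sites plus a site x accession dosage matrix."""
    sites: pd.DataFrame            # chrom, pos, ref, alt
    dosages: np.ndarray            # int8, -1 = missing
    samples: list[str]

    def __post_init__(self):
        d = self.dosages
        if d.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage matrix shape does not match sites x samples")
        if d.max(initial=0) > 2 or d.min(initial=0) < -1:
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    def subset_samples(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in names]
        return self.dosages[:, idx]


def _pop_site_stats(dos: np.ndarray):
    """Per-site (n individuals, alt freq, het fraction) for one population."""
    present = dos >= 0
    n = present.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(present, dos, 0).sum(axis=1) / (2.0 * n)
        h = np.where(present, dos == 1, False).sum(axis=1) / n
    return n, p, h


def wc_fst_components(dos_a: np.ndarray, dos_b: np.ndarray):
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    Two populations, diploid data.  Sites where either population has < 2
    genotyped individuals get NaN components and are excluded from sums.
    """
    n1, p1, h1 = _pop_site_stats(dos_a)
    n2, p2, h2 = _pop_site_stats(dos_b)
    r = 2.0
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1.0) / r * s2
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = ~ok
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


def window_fst(gt: GenotypeTable, populations: Mapping[str, str],
               genome_spec: Mapping[str, int],
               window_bp: int = 1_000_000) -> pd.DataFrame:
    """Windowed W&C Fst: sum(a) / sum(a + b + c) over a window's sites.

    Windows with no usable site or a zero denominator are NaN-flagged
    (``defined`` False).
    """
    pops = sorted(set(populations.values()))
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    members = {p: [s for s in gt.samples if populations[s] == p] for p in pops}
    for p, m in members.items():
        if len(m) < 2:
            raise ValueError(f"population {p!r} needs >= 2 accessions")
    a, b, c = wc_fst_components(gt.subset_samples(members[pops[0]]),
                                gt.subset_samples(members[pops[1]]))
    win = tile_genome(genome_spec, window_bp)
    idx = assign_to_windows(gt.sites["chrom"].to_numpy(),
                            gt.sites["pos"].to_numpy(dtype=np.int64), win)
    num = np.zeros(len(win))
    den = np.zeros(len(win))
    nsnp = np.zeros(len(win), dtype=np.int64)
    ok = (idx >= 0) & ~np.isnan(a)
    np.add.at(num, idx[ok], a[ok])
    np.add.at(den, idx[ok], (a + b + c)[ok])
    np.add.at(nsnp, idx[idx >= 0], 1)
    out = win.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den != 0, num / den, np.nan)
    out["n_snps"] = nsnp
    out["defined"] = den != 0
    return out


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(dosages: np.ndarray) -> float:
    """Tajima's D for one population's dosage block (sites x accessions).

    Dosages are expanded to 2N haplotypes under random mating.  Sites with
    any missing genotype are excluded so that the haplotype count n is
    constant.  Returns NaN (undefined) when n < 4 or no site segregates.
    """
    dos = np.asarray(dosages)
    if dos.ndim == 1:
        dos = dos[:, None]
    complete = (dos >= 0).all(axis=1)
    dos = dos[complete]
    n = 2 * dos.shape[1]
    if n < 4 or dos.shape[0] == 0:
        return float("nan")
    ac = dos.sum(axis=1)
    seg = (ac > 0) & (ac < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    p = ac[seg] / n
    pi_hat = (2.0 * p * (1.0 - p) * n / (n - 1.0)).sum()
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_hat - S / a1) / np.sqrt(var))


def nucleotide_diversity(dosages: np.ndarray, window_length: int) -> float:
    """Per-bp nucleotide diversity pi over a window.

    Each site contributes 2 p (1 - p) n/(n - 1) with site-specific haplotype
    count n (missing genotypes drop that accession at that site); the sum is
    divided by the window length, so monomorphic positions contribute zero.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    dos = np.asarray(dosages)
    if dos.size == 0:
        return 0.0
    present = dos >= 0
    n = 2.0 * present.sum(axis=1)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(present, dos, 0).sum(axis=1) / n
        contrib = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(contrib[ok].sum() / window_length)


def window_pop_stats(gt: GenotypeTable, populations: Mapping[str, str],
                     genome_spec: Mapping[str, int],
                     window_bp: int = 1_000_000) -> pd.DataFrame:
    """Fst plus per-population Tajima's D and pi on the shared window grid."""
    out = window_fst(gt, populations, genome_spec, window_bp)
    win = out[["chrom", "start", "end"]]
    idx = assign_to_windows(gt.sites["chrom"].to_numpy(),
                            gt.sites["pos"].to_numpy(dtype=np.int64), win)
    for pop in sorted(set(populations.values())):
        dos = gt.subset_samples([s for s in gt.samples if populations[s] == pop])
        D = np.full(len(win), np.nan)
        pi = np.zeros(len(win))
        for w in range(len(win)):
            block = dos[idx == w]
            length = int(win.loc[w, "end"] - win.loc[w, "start"])
            if len(block):
                D[w] = tajimas_d(block)
                pi[w] = nucleotide_diversity(block, length)
        out[f"tajima_d_{pop}"] = D
        out[f"pi_{pop}"] = pi
    return out


def call_dsr(window_stats: pd.DataFrame, top_fraction: float = 0.05,
             min_windows: int = 20) -> pd.DataFrame:
    """Windows in the top ``top_fraction`` of Fst (ties at the threshold kept)."""
    defined = window_stats.loc[window_stats["fst"].notna()]
    if len(defined) == 0:
        raise ValueError("all windows have undefined Fst")
    if len(defined) < min_windows:
        raise ValueError(f"need >= {min_windows} defined windows, got {len(defined)}")
    thr = float(np.quantile(defined["fst"].to_numpy(), 1.0 - top_fraction))
    return defined.loc[defined["fst"] >= thr].reset_index(drop=True)


def dsr_genes(dsrs: pd.DataFrame, genes: pd.DataFrame) -> set:
    """Genes overlapping any DSR window by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for _, w in dsrs.iterrows():
        trees.setdefault(w["chrom"], IntervalTree()).addi(int(w["start"]), int(w["end"]))
    hits = set()
    for _, g in genes.iterrows():
        t = trees.get(g["chrom"])
        if t is not None and t.overlap(int(g["start"]), int(g["end"])):
            hits.add(g["gene_id"])
    return hits


def dmr_fst_correlation(window_stats: pd.DataFrame,
                        contexts: Sequence[str] = CONTEXTS) -> dict:
    """Pearson correlation between window Fst and per-context DMR counts.

    Expects ``window_stats`` to carry ``fst`` and ``dmr_count_<context>``
    columns; undefined-Fst windows are dropped.  Zero variance yields an
    undefined-flagged entry.
    """
    defined = window_stats.loc[window_stats["fst"].notna()]
    if len(defined) < 3:
        raise ValueError("need >= 3 defined windows")
    out = {}
    fst = defined["fst"].to_numpy(dtype=float)
    for c in contexts:
        y = defined[f"dmr_count_{c}"].to_numpy(dtype=float)
        if np.std(fst) == 0 or np.std(y) == 0:
            out[c] = {"r": np.nan, "p": np.nan, "defined": False}
        else:
            r, p = stats.pearsonr(fst, y)
            out[c] = {"r": float(r), "p": float(p), "defined": True}
    return out


def overlap_venn(set_a: set, set_b: set) -> dict:
    """Set-algebra counts for the DMR-gene / DSR-gene Venn comparison."""
    return {"only_a": len(set_a - set_b), "only_b": len(set_b - set_a),
            "shared": len(set_a & set_b)}
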