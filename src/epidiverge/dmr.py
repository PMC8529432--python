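"""Differentially methylated region (DMR) detection between two populations.

A DMR is a run of cytosines of one context where the two populations'
pooled methylation levels differ beyond context-specific thresholds:

* every tested cytosine has pooled read coverage > ``min_region_coverage``
  in both populations;
* at least ``min_sites`` differential cytosines, adjacent ones less than
  ``max_gap_bp`` apart, all differing in the same direction;
* the region-level difference in mean methylation exceeds ``min_delta``
  for the context (defaults 0.4 / 0.4 / 0.2 for CG / CHG / CHH);
* Fisher's exact test on the region's pooled methylated/unmethylated
  read counts is significant at ``alpha``.

Direction is reported relative to population A: ``hyper`` means A is the
more methylated population.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methcall import CONTEXTS

DMR_COLUMNS = ["chrom", "start", "end", "context", "n_sites",
               "mean_a", "mean_b", "delta", "p_fisher", "direction"]

# relative tie tolerance when summing hypergeometric probabilities <= the
# observed table's probability (same convention as scipy.stats.fisher_exact)
_TIE_GAMMA = 1.0 + 1e-7


@dataclass
class DmrParams:
    """Thresholds of the DMR definition; defaults follow the criteria above."""
    min_region_coverage: int = 10          # strict: pooled depth must exceed this
    min_sites: int = 3
    max_gap_bp: int = 300
    min_delta: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.4, "CHH": 0.2})
    alpha: float = 0.05
    # 'counts': population level = pooled reads ratio; 'means': mean of
    # per-site level ratios within the region
    level_mode: str = "counts"

    def validate(self) -> None:
        if self.min_sites < 2:
            raise ValueError("min_sites must be >= 2")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")
        for c, d in self.min_delta.items():
            if not 0.0 < d <= 1.0:
                raise ValueError(f"min_delta[{c}] must be in (0, 1], got {d}")


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables [[a, b], [c, d]], vectorized.

    Conditional on the margins the table probability is hypergeometric; the
    two-sided p sums the probabilities of all tables (with the same margins)
    whose probability does not exceed the observed one.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("table cells must be non-negative")
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    p = np.ones(len(a))
    todo = (r1 > 0) & (r1 < n) & (c1 > 0) & (c1 < n)
    if todo.any():
        r1t, c1t, nt, at = r1[todo], c1[todo], n[todo], a[todo]
        lo = np.maximum(0, r1t + c1t - nt)
        hi = np.minimum(r1t, c1t)
        width = int((hi - lo).max()) + 1
        k = lo[:, None] + np.arange(width)[None, :]
        valid = k <= hi[:, None]
        kk = np.where(valid, k, lo[:, None])
        logpmf = stats.hypergeom.logpmf(kk, nt[:, None], r1t[:, None], c1t[:, None])
        logobs = stats.hypergeom.logpmf(at, nt, r1t, c1t)
        pmf = np.where(valid, np.exp(logpmf), 0.0)
        take = pmf <= np.exp(logobs)[:, None] * _TIE_GAMMA
        p[todo] = np.minimum((pmf * take).sum(axis=1), 1.0)
    return p


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a single 2x2 table."""
    (a, b), (c, d) = table
    return float(fisher_exact_many(a, b, c, d)[0])


def pool_population(tables: Mapping[str, pd.DataFrame],
                    populations: Mapping[str, str]) -> dict[str, pd.DataFrame]:
    """Pool per-accession cytosine tables into per-population site tables.

    Sites are keyed by (chrom, pos, strand, context); depth and methylated
    counts are summed over the population's accessions at every site present
    in at least one of them, and ``level`` is the pooled ratio.
    """
    pops = sorted(set(populations.values()))
    out = {}
    for pop in pops:
        members = [acc for acc, p in populations.items() if p == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no accessions")
        missing = [acc for acc in members if acc not in tables]
        if missing:
            raise ValueError(f"population {pop!r} lacks tables for {missing}")
        frames = [tables[acc][["chrom", "pos", "strand", "context", "depth", "meth"]]
                  for acc in members]
        cat = pd.concat(frames, ignore_index=True)
        pooled = (cat.groupby(["chrom", "pos", "strand", "context"],
                              sort=True, observed=True)[["depth", "meth"]]
                  .sum().reset_index())
        pooled["level"] = pooled["meth"] / pooled["depth"]
        out[pop] = pooled
    return out


def _aligned(pooled_a: pd.DataFrame, pooled_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two pooled site tables on (chrom, pos, strand, context)."""
    key = ["chrom", "pos", "strand", "context"]
    if len(pooled_a) == len(pooled_b) and \
            (pooled_a["pos"].to_numpy() == pooled_b["pos"].to_numpy()).all() and \
            (pooled_a["chrom"].to_numpy() == pooled_b["chrom"].to_numpy()).all():
        df = pooled_a[key].copy()
        df["depth_a"] = pooled_a["depth"].to_numpy()
        df["meth_a"] = pooled_a["meth"].to_numpy()
        df["depth_b"] = pooled_b["depth"].to_numpy()
        df["meth_b"] = pooled_b["meth"].to_numpy()
        return df
    return pooled_a[key + ["depth", "meth"]].merge(
        pooled_b[key + ["depth", "meth"]], on=key, suffixes=("_a", "_b"))


def find_dmrs(pooled_a: pd.DataFrame, pooled_b: pd.DataFrame, context: str,
              params: DmrParams | None = None) -> pd.DataFrame:
    """Detect DMRs of one context between pooled populations A and B.

    Candidate cytosines (coverage above threshold in both populations and
    per-site level difference at least ``min_delta`` of the context) are
    chained into regions while consecutive candidates are less than
    ``max_gap_bp`` apart and differ in the same direction; regions are then
    filtered on site count, region-level delta and Fisher's exact test.
    """
    params = params or DmrParams()
    params.validate()
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    min_delta = params.min_delta[context]

    df = _aligned(pooled_a, pooled_b)
    df = df.loc[np.asarray(df["context"]) == context]
    df = df.sort_values(["chrom", "pos"], kind="mergesort")

    depth_a = df["depth_a"].to_numpy(dtype=np.int64)
    depth_b = df["depth_b"].to_numpy(dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = df["meth_a"].to_numpy() / depth_a - df["meth_b"].to_numpy() / depth_b
    cand = ((depth_a > params.min_region_coverage)
            & (depth_b > params.min_region_coverage)
            & (np.abs(diff) >= min_delta))
    sub = df.loc[cand]
    if not len(sub):
        return pd.DataFrame(columns=DMR_COLUMNS)

    pos = sub["pos"].to_numpy(dtype=np.int64)
    chrom = sub["chrom"].to_numpy()
    sign = np.sign(diff[cand])
    new_region = np.ones(len(sub), dtype=bool)
    if len(sub) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) < params.max_gap_bp
        same_sign = sign[1:] == sign[:-1]
        new_region[1:] = ~(same_chrom & close & same_sign)
    region_id = np.cumsum(new_region) - 1

    g = pd.DataFrame({
        "region": region_id, "chrom": chrom, "pos": pos,
        "da": sub["depth_a"].to_numpy(dtype=np.int64),
        "ma": sub["meth_a"].to_numpy(dtype=np.int64),
        "db": sub["depth_b"].to_numpy(dtype=np.int64),
        "mb": sub["meth_b"].to_numpy(dtype=np.int64),
    })
    agg = g.groupby("region").agg(
        chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"),
        n_sites=("pos", "size"), da=("da", "sum"), ma=("ma", "sum"),
        db=("db", "sum"), mb=("mb", "sum"))
    agg["end"] = agg["end"] + 1  # half-open span, last site included

    if params.level_mode == "counts":
        agg["mean_a"] = agg["ma"] / agg["da"]
        agg["mean_b"] = agg["mb"] / agg["db"]
    elif params.level_mode == "means":
        la = g["ma"] / g["da"]
        lb = g["mb"] / g["db"]
        agg["mean_a"] = la.groupby(g["region"]).mean()
        agg["mean_b"] = lb.groupby(g["region"]).mean()
    else:
        raise ValueError(f"unknown level_mode {params.level_mode!r}")
    agg["delta"] = agg["mean_a"] - agg["mean_b"]

    keep = (agg["n_sites"] >= params.min_sites) & (agg["delta"].abs() >= min_delta)
    agg = agg.loc[keep]
    if not len(agg):
        return pd.DataFrame(columns=DMR_COLUMNS)
    agg = agg.copy()
    agg["p_fisher"] = fisher_exact_many(
        agg["ma"].to_numpy(), (agg["da"] - agg["ma"]).to_numpy(),
        agg["mb"].to_numpy(), (agg["db"] - agg["mb"]).to_numpy())
    agg = agg.loc[agg["p_fisher"] < params.alpha]
    agg["context"] = context
    agg["direction"] = np.where(agg["delta"] > 0, "hyper", "hypo")
    return agg[DMR_COLUMNS].reset_index(drop=True)


def find_all_dmrs(pooled_a: pd.DataFrame, pooled_b: pd.DataFrame,
                  params: DmrParams | None = None) -> pd.DataFrame:
    """DMRs of all three contexts, concatenated."""
    parts = [find_dmrs(pooled_a, pooled_b, c, params) for c in CONTEXTS]
    nonempty = [p for p in parts if len(p)]
    if not nonempty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    return pd.concat(nonempty, ignore_index=True)


def summarize_dmrs(dmrs: pd.DataFrame) -> dict:
    """Per-context counts, direction balance, lengths and cross-context overlap.

    ``overlap[c1][c2]`` counts DMRs of context c1 that share at least one
    base pair with some DMR of context c2.
    """
    from intervaltree import IntervalTree

    summary: dict = {"per_context": {}, "overlap": {}}
    trees: dict[str, dict] = {}
    for c in CONTEXTS:
        sub = dmrs.loc[dmrs["context"] == c] if len(dmrs) else dmrs
        lengths = (sub["end"] - sub["start"]) if len(sub) else pd.Series(dtype=float)
        summary["per_context"][c] = {
            "n": int(len(sub)),
            "n_hyper": int((sub["direction"] == "hyper").sum()) if len(sub) else 0,
            "n_hypo": int((sub["direction"] == "hypo").sum()) if len(sub) else 0,
            "mean_length": float(lengths.mean()) if len(sub) else 0.0,
            "median_length": float(lengths.median()) if len(sub) else 0.0,
        }
        trees[c] = {}
        for _, r in (sub.iterrows() if len(sub) else ()):
            trees[c].setdefault(r["chrom"], IntervalTree()).addi(r["start"], r["end"])
    for c1 in CONTEXTS:
        summary["overlap"][c1] = {}
        sub = dmrs.loc[dmrs["context"] == c1] if len(dmrs) else dmrs
        for c2 in CONTEXTS:
            if c1 == c2:
                continue
            n = 0
            for _, r in (sub.iterrows() if len(sub) else ()):
                t = trees[c2].get(r["chrom"])
                if t is not None and t.overlap(r["start"], r["end"]):
                    n += 1
            summary["overlap"][c1][c2] = n
    return summary
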