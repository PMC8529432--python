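"""Synthetic two-population cohort generator.

Emulates the statistical structure of a 5-vs-5 whole-genome bisulfite /
RNA-seq / resequencing cohort from two diverged populations:

* a random reference sequence (GC content 0.44) from which every cytosine
  of both strands is extracted with its CG/CHG/CHH context;
* per-accession methylomes: site level = context baseline, shifted inside
  planted DMRs for one population, overridden in coupled genes' promoter
  windows, jittered per accession with a beta distribution, then observed
  through Poisson depth and binomial methylated counts with a bisulfite
  non-conversion error;
* an unmethylated control sequence ("chloroplast") whose apparent
  methylation is exactly the non-conversion rate;
* a gene/TE annotation with mRNA and lncRNA biotypes;
* an FPKM table in which coupled genes' expression is generated from their
  realized promoter methylation to hit a target Pearson r in expectation;
* biallelic SNP genotypes with Balding-Nichols allele-frequency divergence
  concentrated in designated genomic windows.

Everything is driven by a single seed and recorded in a machine-readable
truth manifest, which downstream scoring uses as the oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as eio
from .methcall import CONTEXTS
from .methexpr import PromoterWindowSpec
from .windows import tile_genome

_BASES = np.array(["A", "C", "G", "T"])
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G on the 0..3 code scale

# per-accession target-level bands for coupled genes, spanning the
# variability-filter cuts of the matching context with some margin
_COUPLING_BANDS = {"CG": (0.10, 0.95), "CHG": (0.10, 0.60), "CHH": (0.005, 0.14)}


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort (defaults: 5 vs 5 accessions,
    17x mean depth, 0.5% non-conversion, context baselines 0.9/0.7/0.03)."""
    genome_spec: Mapping[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_accessions_per_pop: int = 5
    depth_mean: float = 17.0
    nonconversion_rate: float = 0.005
    baseline_levels: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.9, "CHG": 0.7, "CHH": 0.03})
    n_planted_dmrs: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 20, "CHG": 20, "CHH": 20})
    dmr_effect: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.5, "CHH": 0.3})
    dmr_length_bp: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 300, "CHG": 300, "CHH": 300})
    n_genes: int = 200
    frac_lncrna: float = 0.1
    n_tes: int = 100
    n_coupled_genes: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 20, "CHG": 0, "CHH": 20})
    coupling_r: Mapping[str, float] = field(
        default_factory=lambda: {"CG": -0.9, "CHG": -0.9, "CHH": 0.9})
    lncrna_r_boost: float = 0.05
    n_snps: int = 5000
    n_divergent_windows: int = 2
    divergent_fst: float = 0.4
    window_bp: int = 100_000
    dmr_divergent_frac: float = 0.0
    jitter_concentration: float = 50.0
    gc_content: float = 0.44
    control_length_bp: int = 150_000
    seed: int = 0

    def validate(self) -> None:
        for name, v in [("nonconversion_rate", self.nonconversion_rate),
                        ("frac_lncrna", self.frac_lncrna),
                        ("gc_content", self.gc_content),
                        ("dmr_divergent_frac", self.dmr_divergent_frac)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for c in CONTEXTS:
            if not 0.0 <= self.baseline_levels[c] <= 1.0:
                raise ValueError(f"baseline level for {c} out of [0, 1]")
            if self.dmr_length_bp[c] <= 0:
                raise ValueError("dmr_length_bp must be positive")
        if any(l <= 0 for l in self.genome_spec.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_accessions_per_pop < 1:
            raise ValueError("need at least one accession per population")


@dataclass
class TruthManifest:
    """Planted features, 0-based half-open coordinates."""
    planted_dmrs: pd.DataFrame    # chrom, start, end, context, direction, delta
    coupled_genes: pd.DataFrame   # gene_id, context, window_start, window_end, target_r
    divergent_windows: pd.DataFrame  # chrom, start, end, target_fst

    def to_dict(self) -> dict:
        return {k: getattr(self, k).to_dict(orient="records")
                for k in ("planted_dmrs", "coupled_genes", "divergent_windows")}

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        cols = {"planted_dmrs": ["chrom", "start", "end", "context", "direction", "delta"],
                "coupled_genes": ["gene_id", "context", "window_start", "window_end", "target_r"],
                "divergent_windows": ["chrom", "start", "end", "target_fst"]}
        return cls(**{k: pd.DataFrame(d.get(k, []), columns=cols[k]) for k in cols})


@dataclass
class Cohort:
    """In-memory cohort: one shared site table plus count matrices."""
    sites: pd.DataFrame                  # chrom, pos, strand, context, trinucleotide
    depth: np.ndarray                    # int16, sites x accessions
    meth: np.ndarray
    control_sites: pd.DataFrame
    control_depth: np.ndarray
    control_meth: np.ndarray
    accessions: list[str]
    populations: dict[str, str]          # accession -> 'A' | 'B'
    genes: pd.DataFrame
    exons: pd.DataFrame
    tes: pd.DataFrame
    fpkm: pd.DataFrame                   # genes x accessions
    snp_sites: pd.DataFrame
    dosages: np.ndarray
    truth: TruthManifest
    config: SimConfig

    def accession_table(self, accession: str) -> pd.DataFrame:
        j = self.accessions.index(accession)
        out = self.sites[["chrom", "pos", "strand", "context"]].copy()
        out["depth"] = self.depth[:, j].astype(np.int64)
        out["meth"] = self.meth[:, j].astype(np.int64)
        out["trinucleotide"] = self.sites["trinucleotide"]
        return out

    def control_table(self, accession: str) -> pd.DataFrame:
        j = self.accessions.index(accession)
        out = self.control_sites[["chrom", "pos", "strand", "context"]].copy()
        out["depth"] = self.control_depth[:, j].astype(np.int64)
        out["meth"] = self.control_meth[:, j].astype(np.int64)
        out["trinucleotide"] = self.control_sites["trinucleotide"]
        return out

    def accession_tables(self) -> dict[str, pd.DataFrame]:
        return {a: self.accession_table(a) for a in self.accessions}

    def pooled_table(self, pop: str) -> pd.DataFrame:
        """Pooled site table for one population.

        Fast path exploiting the shared site coordinates; equals
        :func:`epidiverge.dmr.pool_population` on the accession tables.
        """
        cols = [j for j, a in enumerate(self.accessions)
                if self.populations[a] == pop]
        if not cols:
            raise ValueError(f"population {pop!r} has no accessions")
        out = self.sites[["chrom", "pos", "strand", "context"]].copy()
        out["depth"] = self.depth[:, cols].astype(np.int64).sum(axis=1)
        out["meth"] = self.meth[:, cols].astype(np.int64).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["level"] = np.where(out["depth"] > 0, out["meth"] / out["depth"], np.nan)
        return out


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _extract_sites(seq: np.ndarray, chrom: str) -> pd.DataFrame:
    """All cytosines of both strands with context and trinucleotide.

    Cytosines within 2 bp of a sequence end are dropped (context undefined).
    """
    L = len(seq)
    idx = np.arange(2, L - 2)
    s = seq[idx]
    rows = []
    # plus strand: C at i, context from i+1, i+2
    plus = idx[s == 1]
    b1, b2 = seq[plus + 1], seq[plus + 2]
    ctx_p = np.where(b1 == 2, 0, np.where(b2 == 2, 1, 2))
    tri_p = (np.char.add(np.char.add(_BASES[np.full(len(plus), 1)], _BASES[b1]), _BASES[b2])
             if len(plus) else np.array([], dtype=str))
    rows.append(pd.DataFrame({"chrom": chrom, "pos": plus, "strand": "+",
                              "context": np.array(CONTEXTS)[ctx_p] if len(plus) else [],
                              "trinucleotide": tri_p}))
    # minus strand: G at i reads as C; context bases are i-1, i-2 complemented
    minus = idx[s == 2]
    c1, c2 = _COMP[seq[minus - 1]], _COMP[seq[minus - 2]]
    ctx_m = np.where(c1 == 2, 0, np.where(c2 == 2, 1, 2))
    tri_m = (np.char.add(np.char.add(_BASES[np.full(len(minus), 1)], _BASES[c1]), _BASES[c2])
             if len(minus) else np.array([], dtype=str))
    rows.append(pd.DataFrame({"chrom": chrom, "pos": minus, "strand": "-",
                              "context": np.array(CONTEXTS)[ctx_m] if len(minus) else [],
                              "trinucleotide": tri_m}))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def _place_genes(rng, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    total = sum(config.genome_spec.values())
    genes, exons = [], []
    gid = 0
    margin = 3500  # room for the 3 kb promoter plus spacing
    for chrom, length in config.genome_spec.items():
        n_here = max(1, round(config.n_genes * length / total)) if config.n_genes else 0
        if gid + n_here > config.n_genes:
            n_here = config.n_genes - gid
        if n_here == 0:
            continue
        slot = length // n_here
        if slot < margin + 2500:
            raise ValueError(
                f"cannot place gene gene{gid:05d}: chromosome {chrom} too short "
                f"for {n_here} genes with promoter margins")
        for k in range(n_here):
            glen = int(rng.integers(1200, 2500))
            start = k * slot + margin
            end = min(start + glen, (k + 1) * slot - 100)
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "lncRNA" if rng.random() < config.frac_lncrna else "mRNA"
            name = f"gene{gid:05d}"
            genes.append((name, chrom, start, end, strand, biotype))
            n_ex = int(rng.integers(1, 4))
            parts = rng.dirichlet(np.ones(2 * n_ex - 1)) * (end - start)
            bounds = np.concatenate([[0], np.cumsum(parts)]).astype(int) + start
            bounds[-1] = end
            for e in range(n_ex):
                es, ee = int(bounds[2 * e]), int(bounds[2 * e + 1])
                if ee > es:
                    exons.append((name, es, ee))
            gid += 1
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                            "strand", "biotype"])
    exons_df = pd.DataFrame(exons, columns=["gene_id", "start", "end"])
    tes = []
    for t in range(config.n_tes):
        chrom = list(config.genome_spec)[int(rng.integers(len(config.genome_spec)))]
        length = config.genome_spec[chrom]
        tlen = int(rng.integers(500, 3000))
        start = int(rng.integers(0, max(1, length - tlen)))
        tes.append((chrom, start, start + tlen, f"TE{t:04d}"))
    tes_df = pd.DataFrame(tes, columns=["chrom", "start", "end", "te_id"])
    return genes_df, exons_df, tes_df


def _site_index(sites: pd.DataFrame):
    """Per-chromosome sorted position arrays + global row offsets."""
    out = {}
    offset = 0
    for chrom, grp in sites.groupby("chrom", sort=False, observed=True):
        out[chrom] = (grp["pos"].to_numpy(), offset)
        offset += len(grp)
    return out


def _rows_in(site_idx, chrom: str, start: int, end: int) -> np.ndarray:
    pos, offset = site_idx[chrom]
    a = np.searchsorted(pos, start, side="left")
    b = np.searchsorted(pos, end, side="left")
    return np.arange(a, b) + offset


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort; the seed determines every output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (seq_seed, gene_seed, dmr_seed, acc_seed, expr_seed,
     snp_seed, ctrl_seed) = ss.spawn(7)

    rng = np.random.default_rng(seq_seed)
    site_frames = []
    for chrom, length in config.genome_spec.items():
        seq = _random_sequence(rng, length, config.gc_content)
        site_frames.append(_extract_sites(seq, chrom))
    sites = pd.concat(site_frames, ignore_index=True)
    ctx_arr = sites["context"].to_numpy()
    site_idx = _site_index(sites)

    rng = np.random.default_rng(gene_seed)
    genes, exons, tes = _place_genes(rng, config)

    # coupled genes: disjoint across contexts, lncRNA boost on |r|
    wspec = PromoterWindowSpec()
    coupled_rows = []
    coupling = {}  # context -> (gene rows, row-index arrays, target levels, target r)
    available = list(genes.index)
    rng.shuffle(available)
    n_acc = 2 * config.n_accessions_per_pop
    cursor = 0
    for c in CONTEXTS:
        need = config.n_coupled_genes.get(c, 0)
        if cursor + need > len(available):
            raise ValueError(f"not enough genes to couple {need} in context {c}")
        chosen = available[cursor:cursor + need]
        cursor += need
        entries = []
        lo, hi = _COUPLING_BANDS[c]
        for gi in chosen:
            g = genes.loc[gi]
            ws, we = wspec.interval(g, c, config.genome_spec[g["chrom"]])
            rows = _rows_in(site_idx, g["chrom"], ws, we)
            rows = rows[ctx_arr[rows] == c]
            levels = np.linspace(lo, hi, n_acc)
            rng.shuffle(levels)
            r_t = config.coupling_r[c]
            if g["biotype"] == "lncRNA":
                r_t = float(np.sign(r_t) * min(0.99, abs(r_t) + config.lncrna_r_boost))
            coupled_rows.append((g["gene_id"], c, int(ws), int(we), r_t))
            entries.append((gi, rows, levels, r_t))
        coupling[c] = entries
    coupled_df = pd.DataFrame(
        coupled_rows, columns=["gene_id", "context", "window_start", "window_end", "target_r"])

    # divergent windows on the analysis grid
    rng = np.random.default_rng(snp_seed)
    grid = tile_genome(config.genome_spec, config.window_bp)
    if config.n_divergent_windows > len(grid):
        raise ValueError("more divergent windows requested than grid windows")
    div_idx = rng.choice(len(grid), size=config.n_divergent_windows, replace=False)
    div_windows = grid.loc[sorted(div_idx)].reset_index(drop=True)
    div_windows["target_fst"] = config.divergent_fst

    # planted DMRs
    rng = np.random.default_rng(dmr_seed)
    chroms = list(config.genome_spec)
    lengths = np.array([config.genome_spec[c] for c in chroms], dtype=float)
    pchrom = lengths / lengths.sum()
    blocked = {c: [] for c in CONTEXTS}   # intervals occupied per context
    for c, entries in coupling.items():
        for gi, rows, _, _ in entries:
            g = genes.loc[gi]
            ws, we = wspec.interval(g, c, config.genome_spec[g["chrom"]])
            blocked[c].append((g["chrom"], ws, we))
    dmr_rows = []
    shiftA = np.zeros(len(sites), dtype=np.float32)
    shiftB = np.zeros(len(sites), dtype=np.float32)
    for c in CONTEXTS:
        n_want = config.n_planted_dmrs.get(c, 0)
        eff = config.dmr_effect[c]
        dlen = config.dmr_length_bp[c]
        if n_want and eff > 0:
            base = config.baseline_levels[c]
            sign = +1.0 if base + eff <= 1.0 else -1.0  # hyper shift if room, else hypo
            n_div = int(round(config.dmr_divergent_frac * n_want))
            placed = 0
            tries = 0
            while placed < n_want:
                tries += 1
                if tries > 200 * n_want:
                    raise RuntimeError(
                        f"cannot place planted DMR {placed} of context {c}: genome capacity exhausted")
                if placed < n_div and len(div_windows):
                    w = div_windows.iloc[int(rng.integers(len(div_windows)))]
                    chrom = w["chrom"]
                    if w["end"] - w["start"] <= dlen:
                        continue
                    start = int(rng.integers(w["start"], w["end"] - dlen))
                else:
                    chrom = chroms[int(rng.choice(len(chroms), p=pchrom))]
                    if config.genome_spec[chrom] <= dlen:
                        continue
                    start = int(rng.integers(0, config.genome_spec[chrom] - dlen))
                end = start + dlen
                if any(ch == chrom and s < end and start < e
                       for ch, s, e in blocked[c]):
                    continue
                rows = _rows_in(site_idx, chrom, start, end)
                rows = rows[ctx_arr[rows] == c]
                if len(rows) < 4:
                    continue
                pos_sel = sites["pos"].to_numpy()[rows]
                t_start, t_end = int(pos_sel.min()), int(pos_sel.max()) + 1
                shifted_pop = "A" if rng.random() < 0.5 else "B"
                if shifted_pop == "A":
                    shiftA[rows] += sign * eff
                else:
                    shiftB[rows] += sign * eff
                delta = sign * eff if shifted_pop == "A" else -sign * eff
                direction = "hyper" if delta > 0 else "hypo"
                dmr_rows.append((chrom, t_start, t_end, c, direction, delta))
                blocked[c].append((chrom, t_start, t_end))
                placed += 1
    planted_df = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "context", "direction", "delta"])

    # per-accession counts
    base = np.empty(len(sites), dtype=np.float32)
    for i, c in enumerate(CONTEXTS):
        base[ctx_arr == c] = config.baseline_levels[c]
    accessions = [f"A{i+1}" for i in range(config.n_accessions_per_pop)] + \
                 [f"B{i+1}" for i in range(config.n_accessions_per_pop)]
    populations = {a: a[0] for a in accessions}
    n_sites = len(sites)
    depth = np.zeros((n_sites, n_acc), dtype=np.int16)
    meth = np.zeros((n_sites, n_acc), dtype=np.int16)
    acc_children = acc_seed.spawn(n_acc)
    e = config.nonconversion_rate
    conc = config.jitter_concentration
    realized: dict[str, np.ndarray] = {
        c: np.zeros((len(coupling[c]), n_acc)) for c in CONTEXTS}
    for j, acc in enumerate(accessions):
        arng = np.random.default_rng(acc_children[j])
        lvl = base + (shiftA if populations[acc] == "A" else shiftB)
        lvl = np.clip(lvl, 0.0, 1.0).astype(np.float64)
        for c, entries in coupling.items():
            for k, (gi, rows, levels, r_t) in enumerate(entries):
                lvl[rows] = levels[j]
        m = np.clip(lvl, 1e-6, 1 - 1e-6)
        jit = arng.beta(m * conc, (1.0 - m) * conc)
        apparent = jit + (1.0 - jit) * e
        d = arng.poisson(config.depth_mean, size=n_sites)
        mm = arng.binomial(d, apparent)
        depth[:, j] = d
        meth[:, j] = mm
        for c, entries in coupling.items():
            for k, (gi, rows, levels, r_t) in enumerate(entries):
                dsum = d[rows].sum()
                realized[c][k, j] = mm[rows].sum() / dsum if dsum > 0 else np.nan

    # control ("chloroplast"): fully unmethylated
    crng = np.random.default_rng(ctrl_seed)
    cseq = _random_sequence(crng, config.control_length_bp, config.gc_content)
    control_sites = _extract_sites(cseq, "chloroplast")
    cd = crng.poisson(config.depth_mean, size=(len(control_sites), n_acc)).astype(np.int16)
    cm = crng.binomial(cd.astype(np.int64), e).astype(np.int16)

    # expression
    erng = np.random.default_rng(expr_seed)
    logf = erng.uniform(0.0, 11.0, size=len(genes))[:, None] + \
        erng.normal(0.0, 0.5, size=(len(genes), n_acc))
    fpkm = np.maximum(np.exp2(logf) - 1.0, 0.0)
    for c, entries in coupling.items():
        for k, (gi, rows, levels, r_t) in enumerate(entries):
            mreal = realized[c][k]
            ok = ~np.isnan(mreal)
            z = np.zeros(n_acc)
            if ok.sum() >= 2 and np.std(mreal[ok]) > 0:
                z[ok] = (mreal[ok] - mreal[ok].mean()) / mreal[ok].std()
            eps = erng.normal(0.0, 1.0, size=n_acc)
            y = r_t * z + np.sqrt(max(0.0, 1.0 - r_t**2)) * eps
            row = np.maximum(np.exp2(5.0 + 1.5 * y) - 1.0, 0.0)
            fpkm[genes.index.get_loc(gi)] = row
    fpkm_df = pd.DataFrame(fpkm, index=genes["gene_id"].to_numpy(), columns=accessions)

    # genotypes
    grng = np.random.default_rng(snp_seed.spawn(1)[0])
    snp_frames = []
    dos_blocks = []
    total = sum(config.genome_spec.values())
    for chrom, length in config.genome_spec.items():
        n_here = max(0, round(config.n_snps * length / total))
        pos = np.sort(grng.choice(length, size=min(n_here, length), replace=False))
        in_div = np.zeros(len(pos), dtype=bool)
        for _, w in div_windows.iterrows():
            if w["chrom"] == chrom:
                in_div |= (pos >= w["start"]) & (pos < w["end"])
        p_anc = grng.uniform(0.05, 0.95, size=len(pos))
        pA = p_anc.copy()
        pB = p_anc.copy()
        if in_div.any() and config.divergent_fst > 0:
            F = config.divergent_fst
            shape = (1.0 - F) / F
            pa = p_anc[in_div]
            pA[in_div] = grng.beta(pa * shape, (1 - pa) * shape)
            pB[in_div] = grng.beta(pa * shape, (1 - pa) * shape)
        nA = config.n_accessions_per_pop
        dA = grng.binomial(2, pA[:, None], size=(len(pos), nA))
        dB = grng.binomial(2, pB[:, None], size=(len(pos), nA))
        ref_alt = grng.integers(0, 4, size=(len(pos), 2))
        ref_alt[:, 1] = (ref_alt[:, 0] + 1 + grng.integers(0, 3, size=len(pos))) % 4
        snp_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": _BASES[ref_alt[:, 0]], "alt": _BASES[ref_alt[:, 1]]}))
        dos_blocks.append(np.hstack([dA, dB]).astype(np.int8))
    snp_sites = pd.concat(snp_frames, ignore_index=True)
    dosages = np.vstack(dos_blocks) if dos_blocks else np.zeros((0, n_acc), dtype=np.int8)

    truth = TruthManifest(planted_dmrs=planted_df, coupled_genes=coupled_df,
                          divergent_windows=div_windows[["chrom", "start", "end", "target_fst"]])
    return Cohort(sites=sites, depth=depth, meth=meth,
                  control_sites=control_sites, control_depth=cd, control_meth=cm,
                  accessions=accessions, populations=populations,
                  genes=genes, exons=exons, tes=tes, fpkm=fpkm_df,
                  snp_sites=snp_sites, dosages=dosages, truth=truth, config=config)


def write_fixtures(cohort: Cohort, directory) -> dict[str, Path]:
    """Write the cohort as the pipeline's input file set; returns the paths."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"cannot write fixtures to {directory}: {exc}") from exc
    paths: dict[str, Path] = {}
    for acc in cohort.accessions:
        p = d / f"{acc}.cytosine_report.tsv"
        eio.write_cytosine_report(cohort.accession_table(acc), p)
        paths[f"report_{acc}"] = p
        p = d / f"{acc}.control_report.tsv"
        eio.write_cytosine_report(cohort.control_table(acc), p)
        paths[f"control_{acc}"] = p
    paths["gff3"] = d / "annotation.gff3"
    eio.write_gff3(cohort.genes, cohort.exons, paths["gff3"])
    paths["tes"] = d / "tes.bed"
    eio.write_bed(cohort.tes, paths["tes"], name_col="te_id")
    paths["vcf"] = d / "genotypes.vcf"
    eio.write_vcf(cohort.snp_sites, cohort.dosages, cohort.accessions,
                  paths["vcf"], cohort.config.genome_spec)
    paths["fpkm"] = d / "fpkm.tsv"
    eio.write_fpkm(cohort.fpkm, paths["fpkm"])
    paths["populations"] = d / "populations.tsv"
    eio.write_populations(cohort.populations, paths["populations"])
    paths["truth"] = d / "truth.json"
    eio.write_json(cohort.truth.to_dict(), paths["truth"])
    paths["config"] = d / "sim_config.json"
    cfg = asdict(cohort.config)
    cfg["genome_spec"] = dict(cfg["genome_spec"])
    eio.write_json(cfg, paths["config"])
    return paths
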