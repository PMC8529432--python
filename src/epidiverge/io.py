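"""Readers and writers for the pipeline's on-disk formats.

Cytosine reports follow the Bismark cytosine-report dialect: TSV with
columns chrom, pos (1-based), strand, methylated count, unmethylated count,
context, trinucleotide.  Internally all coordinates are 0-based half-open.
Annotations are GFF3 (genes with exon children, ``biotype`` attribute),
TEs a BED file, genotypes VCF 4.2 with GT fields, expression a gene x
accession FPKM TSV.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]


def read_cytosine_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=REPORT_COLUMNS,
                     dtype={"chrom": str, "pos": np.int64, "strand": str,
                            "meth": np.int64, "unmeth": np.int64,
                            "context": str, "trinucleotide": str})
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"] - 1,
        "strand": df["strand"],
        "context": df["context"],
        "depth": df["meth"] + df["unmeth"],
        "meth": df["meth"],
        "trinucleotide": df["trinucleotide"],
    })
    return out


def write_cytosine_report(table: pd.DataFrame, path) -> None:
    tri = table["trinucleotide"] if "trinucleotide" in table else "NNN"
    out = pd.DataFrame({
        "chrom": table["chrom"], "pos": table["pos"] + 1, "strand": table["strand"],
        "meth": table["meth"], "unmeth": table["depth"] - table["meth"],
        "context": table["context"], "trinucleotide": tri,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_calls(calls: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "strand", "context", "depth", "meth", "p", "q", "methylated"]
    calls[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exon_by_gene = dict(tuple(exons.groupby("gene_id"))) if len(exons) else {}
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};biotype={g['biotype']}"
            fh.write(f"{g['chrom']}\tsim\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                     f"{g['strand']}\t.\t{attrs}\n")
            ex = exon_by_gene.get(g["gene_id"])
            if ex is None:
                continue
            for j, (_, e) in enumerate(ex.sort_values("start").iterrows(), 1):
                fh.write(f"{g['chrom']}\tsim\texon\t{e['start'] + 1}\t{e['end']}\t.\t"
                         f"{g['strand']}\t.\tID={g['gene_id']}.exon{j};"
                         f"Parent={g['gene_id']}\n")


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genes and exons from GFF3 (via gffutils, in-memory db)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        genes.append((g.id, g.seqid, g.start - 1, g.end, g.strand,
                      g.attributes.get("biotype", ["mRNA"])[0]))
    for e in db.features_of_type("exon"):
        parent = e.attributes.get("Parent", [""])[0]
        exons.append((parent, e.start - 1, e.end))
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                            "strand", "biotype"])
    exons_df = pd.DataFrame(exons, columns=["gene_id", "start", "end"])
    return genes_df, exons_df


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = intervals[["chrom", "start", "end"]].copy()
    if name_col is not None:
        cols["name"] = intervals[name_col]
    cols.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end", "te_id")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = list(names)[: df.shape[1]]
    return df


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+ DMR track: name=context:index, score=-log10 p, extra columns."""
    with open(path, "w") as fh:
        for i, d in dmrs.iterrows():
            score = -np.log10(max(d["p_fisher"], 1e-300))
            fh.write(f"{d['chrom']}\t{d['start']}\t{d['end']}\t{d['context']}:{i}\t"
                     f"{score:.3f}\t.\t{d['delta']:.4f}\t{d['mean_a']:.4f}\t"
                     f"{d['mean_b']:.4f}\t{d['n_sites']}\t{d['direction']}\n")


def write_vcf(sites: pd.DataFrame, dosages: np.ndarray, samples, path,
              genome_spec: Mapping[str, int] | None = None) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epidiverge-sim\n")
        if genome_spec:
            for chrom, length in genome_spec.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, s in sites.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in dosages[i])
            fh.write(f"{s['chrom']}\t{s['pos'] + 1}\t.\t{s['ref']}\t{s['alt']}\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a biallelic-SNP VCF into (sites, dosages, samples) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dos = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        g = np.asarray(v.gt_types, dtype=np.int8)  # 0=hom ref,1=het,2=hom alt,3=missing
        g[g == 3] = -1
        dos.append(g)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.vstack(dos) if dos else np.zeros((0, len(samples)), dtype=np.int8)
    return sites, dosages, samples


def write_fpkm(fpkm: pd.DataFrame, path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def read_fpkm(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_populations(populations: Mapping[str, str], path) -> None:
    pd.Series(populations, name="population").to_csv(path, sep="\t",
                                                     index_label="accession")


def read_populations(path) -> dict:
    return pd.read_csv(path, sep="\t", index_col="accession")["population"].to_dict()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    return json.loads(Path(path).read_text())
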