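"""Feature assignment, DMR-genes, window densities, TSS distributions."""
import numpy as np
import pandas as pd
import pytest

from epidiverge.annotate import (assign_features, density_correlation,
                                 dmr_genes, tss_relative_distribution,
                                 window_density)
from epidiverge.windows import tile_genome


@pytest.fixture()
def annotation():
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [10_000, 30_000, 60_000],
        "end": [14_000, 33_000, 64_000],
        "strand": ["+", "-", "+"],
        "biotype": ["mRNA", "mRNA", "lncRNA"]})
    exons = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2", "g3"],
        "start": [10_000, 12_000, 30_000, 60_000],
        "end": [11_000, 14_000, 33_000, 64_000]})
    tes = pd.DataFrame({"chrom": ["chr1"], "start": [45_000], "end": [46_000],
                        "te_id": ["TE1"]})
    return genes, exons, tes


def _dmr(start, end, context="CG", chrom="chr1"):
    return {"chrom": chrom, "start": start, "end": end, "context": context,
            "direction": "hyper"}


class TestAssignFeatures:
    def test_dmr_inside_exon(self, annotation):
        genes, exons, tes = annotation
        out = assign_features(pd.DataFrame([_dmr(10_100, 10_200)]), genes, exons, tes)
        assert out.loc[0, "feature"] == "exon"

    def test_intron_between_exons(self, annotation):
        genes, exons, tes = annotation
        out = assign_features(pd.DataFrame([_dmr(11_200, 11_400)]), genes, exons, tes)
        assert out.loc[0, "feature"] == "intron"

    def test_promoter_beats_exon(self, annotation):
        # spans g1's promoter (upstream of 10 kb) and g1's first exon
        genes, exons, tes = annotation
        out = assign_features(pd.DataFrame([_dmr(9_900, 10_100)]), genes, exons, tes)
        assert out.loc[0, "feature"] == "promoter"

    def test_minus_strand_promoter_is_downstream(self, annotation):
        genes, exons, tes = annotation
        out = assign_features(pd.DataFrame([_dmr(33_500, 33_600)]), genes, exons, tes)
        assert out.loc[0, "feature"] == "promoter"
        assert out.loc[0, "feature_id"] == "g2"

    def test_te_and_intergenic(self, annotation):
        genes, exons, tes = annotation
        out = assign_features(pd.DataFrame([_dmr(45_500, 45_600),
                                            _dmr(50_000, 50_100)]),
                              genes, exons, tes)
        assert list(out["feature"]) == ["TE", "intergenic"]

    def test_zero_length_gene_rejected(self, annotation):
        genes, exons, tes = annotation
        bad = genes.copy()
        bad.loc[0, "end"] = bad.loc[0, "start"]
        with pytest.raises(ValueError):
            assign_features(pd.DataFrame([_dmr(0, 10)]), bad, exons, tes)

    def test_assignment_partitions_dmr_set(self, annotation):
        genes, exons, tes = annotation
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 70_000, size=200)
        dmrs = pd.DataFrame([_dmr(s, s + 50) for s in starts])
        out = assign_features(dmrs, genes, exons, tes)
        assert out["feature"].value_counts().sum() == len(dmrs)


class TestDmrGenes:
    def test_flank_boundary_half_open(self, annotation):
        genes, _, _ = annotation
        # g1 spans [10k, 14k); 3 kb flank reaches [7k, 17k)
        inside = dmr_genes(pd.DataFrame([_dmr(16_999, 17_100)]), genes)
        outside = dmr_genes(pd.DataFrame([_dmr(17_000, 17_100)]), genes)
        assert "g1" in inside["by_context"]["CG"]
        assert "g1" not in outside["by_context"]["CG"]

    def test_monotone_in_flank(self, annotation):
        genes, _, _ = annotation
        rng = np.random.default_rng(8)
        dmrs = pd.DataFrame([_dmr(int(s), int(s) + 100)
                             for s in rng.integers(0, 70_000, size=100)])
        near = dmr_genes(dmrs, genes, flank_bp=0)
        far = dmr_genes(dmrs, genes, flank_bp=3000)
        for c in ("CG", "CHG", "CHH"):
            assert near["by_context"][c] <= far["by_context"][c]

    def test_matches_quadratic_scan(self, annotation):
        genes, _, _ = annotation
        rng = np.random.default_rng(9)
        dmrs = pd.DataFrame([_dmr(int(s), int(s) + 200, context=c)
                             for s, c in zip(rng.integers(0, 70_000, size=150),
                                             rng.choice(["CG", "CHG", "CHH"], 150))])
        got = dmr_genes(dmrs, genes, flank_bp=3000)
        for c in ("CG", "CHG", "CHH"):
            expect = set()
            for _, g in genes.iterrows():
                for _, d in dmrs.loc[dmrs["context"] == c].iterrows():
                    if d["start"] < g["end"] + 3000 and g["start"] - 3000 < d["end"]:
                        expect.add(g["gene_id"])
            assert got["by_context"][c] == expect


class TestWindowDensity:
    GENOME = {"chr1": 3_500_000}

    def test_empty_items_all_zero(self):
        out = window_density(pd.DataFrame(columns=["chrom", "start"]), self.GENOME)
        assert (out["count"] == 0).all()
        assert len(out) == 4  # final partial window kept

    def test_one_item_per_window(self):
        items = pd.DataFrame({"chrom": "chr1",
                              "start": [0, 1_000_000, 2_000_000, 3_000_000]})
        out = window_density(items, self.GENOME)
        assert (out["count"] == 1).all()

    def test_counts_match_bruteforce_and_conserve(self):
        rng = np.random.default_rng(2)
        items = pd.DataFrame({"chrom": "chr1",
                              "start": rng.integers(0, 3_500_000, size=500)})
        out = window_density(items, self.GENOME)
        assert out["count"].sum() == len(items)
        for _, w in out.iterrows():
            n = ((items["start"] >= w["start"]) & (items["start"] < w["end"])).sum()
            assert w["count"] == n


class TestTssDistribution:
    def test_plus_strand_upstream_bin(self, annotation):
        genes, _, _ = annotation
        # midpoint 150 bp upstream of g1's TSS (10 kb)
        dmrs = pd.DataFrame([_dmr(9_800, 9_900)])
        hist = tss_relative_distribution(dmrs, genes)
        assert hist["CG"]["upstream"][1] == 1.0

    def test_minus_strand_downstream_counts_upstream(self, annotation):
        genes, _, _ = annotation
        # g2 on minus strand ends at 33 kb; 150 bp beyond is upstream of TSS
        dmrs = pd.DataFrame([_dmr(33_100, 33_200)])
        hist = tss_relative_distribution(dmrs, genes)
        assert hist["CG"]["upstream"][1] == 1.0

    def test_body_bin_orientation(self, annotation):
        genes, _, _ = annotation
        # near the 5' end of minus-strand g2 -> early body bins
        dmrs = pd.DataFrame([_dmr(32_800, 32_900)])
        hist = tss_relative_distribution(dmrs, genes)
        assert hist["CG"]["body"][:2].sum() == 1.0


class TestDensityCorrelation:
    def test_proportional_counts_r_one(self):
        x = np.arange(10.0)
        assert density_correlation(x, 3 * x)["r"] == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        out = density_correlation(np.arange(10.0), np.ones(10))
        assert not out["defined"]
        assert np.isnan(out["r"])

    def test_planted_proportionality_recovered(self):
        rng = np.random.default_rng(6)
        gene_counts = rng.poisson(20, size=50)
        dmr_counts = rng.poisson(gene_counts * 2.0)
        assert density_correlation(gene_counts, dmr_counts)["r"] > 0.5


def test_tile_genome_partial_window():
    win = tile_genome({"chrA": 2_400_000}, 1_000_000)
    assert list(win["end"] - win["start"]) == [1_000_000, 1_000_000, 400_000]
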