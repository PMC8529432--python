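"""Promoter-window methylation vs expression coupling."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from epidiverge.methexpr import (PromoterWindowSpec, VariabilityFilter,
                                 _masked_rowwise_pearson, biotype_contrast,
                                 correlate_gene, passes_variability_filter,
                                 promoter_window_level, sign_enrichment)

GENE_PLUS = {"gene_id": "g", "chrom": "chr1", "start": 5_000, "end": 7_000,
             "strand": "+", "biotype": "mRNA"}
GENE_MINUS = {"gene_id": "g", "chrom": "chr1", "start": 5_000, "end": 7_000,
              "strand": "-", "biotype": "mRNA"}


def _sites(pos, depth, meth, context="CG"):
    return pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                         "context": context, "depth": depth, "meth": meth})


class TestPromoterWindowLevel:
    def test_no_sites_is_missing(self):
        lvl = promoter_window_level(_sites([100], [10], [5]), GENE_PLUS, "CG")
        assert np.isnan(lvl)

    def test_single_site(self):
        lvl = promoter_window_level(_sites([4_900], [10], [7]), GENE_PLUS, "CG")
        assert lvl == pytest.approx(0.7)

    def test_window_is_strand_oriented(self):
        # for a minus-strand gene the 0-200 window sits beyond the end coord
        sites = _sites([7_100], [10], [9])
        assert np.isnan(promoter_window_level(sites, GENE_PLUS, "CG"))
        assert promoter_window_level(sites, GENE_MINUS, "CG") == pytest.approx(0.9)

    def test_chh_window_offset(self):
        # CHH window is 200-1000 bp upstream: 4900 is too close, 4500 inside
        near = _sites([4_900], [10], [5], context="CHH")
        far = _sites([4_500], [10], [5], context="CHH")
        assert np.isnan(promoter_window_level(near, GENE_PLUS, "CHH"))
        assert promoter_window_level(far, GENE_PLUS, "CHH") == pytest.approx(0.5)

    def test_pooled_ratio_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        pos = np.arange(4_800, 5_000, 13)
        depth = rng.poisson(15, len(pos)) + 1
        meth = rng.binomial(depth, 0.4)
        lvl = promoter_window_level(_sites(pos, depth, meth), GENE_PLUS, "CG")
        assert lvl == pytest.approx(meth.sum() / depth.sum(), rel=1e-12)


class TestVariabilityFilter:
    @pytest.mark.parametrize("context,levels,expected", [
        ("CG", [0.1, 0.9], True),
        ("CG", [0.5, 0.6], False),
        ("CG", [0.1, 0.5], False),       # never exceeds the high cut
        ("CHH", [0.01, 0.05, 0.15], True),
        ("CHG", [0.1, 0.6], True),
    ])
    def test_cases(self, context, levels, expected):
        assert passes_variability_filter(levels, context) is expected

    def test_single_observation_fails(self):
        assert passes_variability_filter([0.1], "CG") is False

    def test_bad_cuts_rejected(self):
        with pytest.raises(ValueError):
            VariabilityFilter(cuts={"CG": (0.8, 0.2)}).validate()


class TestCorrelateGene:
    def test_perfect_anticorrelation(self):
        levels = np.linspace(0.1, 0.9, 8)
        fpkm = np.exp2(10 - 8 * levels) - 1  # log2(FPKM+1) linear in level
        gc = correlate_gene(levels, fpkm)
        assert gc.r == pytest.approx(-1.0, abs=1e-9)

    def test_constant_expression_flagged(self):
        gc = correlate_gene(np.linspace(0, 1, 6), np.full(6, 10.0))
        assert not gc.defined and "variance" in gc.reason

    def test_too_few_pairs_skipped(self):
        gc = correlate_gene([0.1, np.nan, 0.5, np.nan, np.nan, 0.9],
                            np.arange(6.0), min_n=5)
        assert not gc.defined and gc.n == 3

    def test_accession_order_invariance(self):
        rng = np.random.default_rng(1)
        levels = rng.random(10)
        fpkm = rng.random(10) * 100
        perm = rng.permutation(10)
        a = correlate_gene(levels, fpkm)
        b = correlate_gene(levels[perm], fpkm[perm])
        assert a.r == pytest.approx(b.r, rel=1e-12)


class TestRowwisePearson:
    def test_matches_scipy_with_missing_cells(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 10))
        X[rng.random(X.shape) < 0.2] = np.nan
        Y = rng.random((40, 10))
        r, p = _masked_rowwise_pearson(X, Y)
        for i in range(40):
            ok = ~np.isnan(X[i])
            if ok.sum() < 3 or np.std(X[i, ok]) == 0:
                assert np.isnan(r[i])
                continue
            rr, pp = sstats.pearsonr(X[i, ok], Y[i, ok])
            assert r[i] == pytest.approx(rr, rel=1e-9)
            assert p[i] == pytest.approx(pp, rel=1e-6)


class TestSignEnrichment:
    def _coupled_data(self, n_genes=60, n_acc=10, sign=-1.0, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.random((n_genes, n_acc))
        noise = 0.05 * rng.standard_normal(X.shape)
        logf = 8 + sign * 5 * X + noise
        fpkm = np.exp2(logf) - 1
        idx = [f"g{i}" for i in range(n_genes)]
        cols = [f"a{j}" for j in range(n_acc)]
        return (pd.DataFrame(X, index=idx, columns=cols),
                pd.DataFrame(fpkm, index=idx, columns=cols))

    def test_planted_negative_coupling_detected(self):
        levels, fpkm = self._coupled_data(sign=-1.0)
        res = sign_enrichment(levels, fpkm, n_permutations=200, seed=0)
        assert res["observed_negative"] == len(levels)
        assert res["p_negative"] < 0.05

    def test_seed_reproducibility(self):
        levels, fpkm = self._coupled_data()
        a = sign_enrichment(levels, fpkm, n_permutations=50, seed=5)
        b = sign_enrichment(levels, fpkm, n_permutations=50, seed=5)
        assert a == b

    def test_empty_input_is_empty_result_not_error(self):
        res = sign_enrichment(pd.DataFrame(), pd.DataFrame())
        assert res["n_genes"] == 0 and np.isnan(res["p_negative"])

    def test_null_data_not_enriched(self):
        rng = np.random.default_rng(9)
        idx = [f"g{i}" for i in range(80)]
        cols = [f"a{j}" for j in range(10)]
        levels = pd.DataFrame(rng.random((80, 10)), index=idx, columns=cols)
        fpkm = pd.DataFrame(rng.random((80, 10)) * 50, index=idx, columns=cols)
        res = sign_enrichment(levels, fpkm, n_permutations=300, seed=1)
        null = np.asarray(res["null_negative"])
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= res["observed_negative"] <= hi


class TestBiotypeContrast:
    def _corr_frame(self, r_mrna, r_lnc):
        rows = ([("m%d" % i, "CG", r, 0.001, 10, "mRNA") for i, r in enumerate(r_mrna)]
                + [("l%d" % i, "CG", r, 0.001, 10, "lncRNA") for i, r in enumerate(r_lnc)])
        return pd.DataFrame(rows, columns=["gene_id", "context", "r", "p", "n", "biotype"])

    def test_stronger_lncrna_coupling_detected(self):
        corr = self._corr_frame([0.5, 0.55, 0.6, -0.5], [0.9, -0.95, 0.92])
        out = biotype_contrast(corr)
        assert out["by_biotype"]["lncRNA"]["median_abs_r"] > \
            out["by_biotype"]["mRNA"]["median_abs_r"]

    def test_absent_biotype_flagged_partial(self):
        out = biotype_contrast(self._corr_frame([0.5, 0.6], []))
        assert any("partial" in f for f in out["flags"])
        assert np.isnan(out["rank_sum"]["p"])

    def test_single_gene_flagged_underpowered(self):
        out = biotype_contrast(self._corr_frame([0.5, 0.6], [0.9]))
        assert any("underpowered" in f for f in out["flags"])
        assert np.isfinite(out["rank_sum"]["p"])
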