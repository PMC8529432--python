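"""DMR detection: Fisher test, pooling, chaining rules, invariants."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from epidiverge.dmr import (DmrParams, find_all_dmrs, find_dmrs, fisher_exact,
                            fisher_exact_many, pool_population, summarize_dmrs)
from oracles import fisher_enum


def _pooled(pos, depth_meth, context="CG", chrom="chr1"):
    depth, meth = zip(*depth_meth)
    return pd.DataFrame({"chrom": chrom, "pos": list(pos), "strand": "+",
                         "context": context,
                         "depth": list(depth), "meth": list(meth)})


class TestFisher:
    def test_extreme_table(self):
        # both extreme tables have probability 1/C(20,10)
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / 184756, rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_margin_p_one(self):
        assert fisher_exact([[0, 0], [3, 7]]) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(0)
        cells = rng.integers(0, 16, size=(500, 4))
        p = fisher_exact_many(*cells.T)
        expected = [fisher_enum(*row) for row in cells]
        assert np.max(np.abs(p - expected)) < 1e-9

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        cells = rng.integers(0, 40, size=(200, 4))
        p = fisher_exact_many(*cells.T)
        expected = [sstats.fisher_exact([[a, b], [c, d]])[1] for a, b, c, d in cells]
        assert np.max(np.abs(p - expected)) < 1e-9


class TestPooling:
    def test_single_accession_identity(self, toy_sites):
        pooled = pool_population({"x": toy_sites}, {"x": "A"})["A"]
        merged = pooled.merge(toy_sites, on=["chrom", "pos", "strand", "context"])
        assert (merged["depth_x"] == merged["depth_y"]).all()
        assert (merged["meth_x"] == merged["meth_y"]).all()

    def test_two_accessions_sum(self):
        t = _pooled([100], [(10, 5)])
        pooled = pool_population({"x": t, "y": t.copy()}, {"x": "A", "y": "A"})["A"]
        assert pooled.loc[0, "depth"] == 20
        assert pooled.loc[0, "level"] == 0.5

    def test_empty_population_raises(self, toy_sites):
        with pytest.raises(ValueError):
            pool_population({"x": toy_sites}, {"x": "A", "ghost": "B"})

    def test_matches_bruteforce_sum(self, toy_sites):
        rng = np.random.default_rng(5)
        tabs = {}
        for acc in ("a1", "a2", "a3"):
            t = toy_sites.copy()
            t["depth"] = rng.poisson(15, size=len(t)) + 1
            t["meth"] = rng.binomial(t["depth"], 0.4)
            tabs[acc] = t
        pooled = pool_population(tabs, {a: "A" for a in tabs})["A"]
        for _, row in pooled.sample(25, random_state=0).iterrows():
            d = m = 0
            for t in tabs.values():
                hit = t.loc[(t["pos"] == row["pos"]) & (t["strand"] == row["strand"])]
                d += hit["depth"].sum()
                m += hit["meth"].sum()
            assert row["depth"] == d and row["meth"] == m


class TestFindDmrs:
    def test_three_site_example(self):
        a = _pooled([100, 200, 300], [(20, 18)] * 3)
        b = _pooled([100, 200, 300], [(20, 2)] * 3)
        d = find_dmrs(a, b, "CG")
        assert len(d) == 1
        row = d.iloc[0]
        assert row["n_sites"] == 3
        assert row["delta"] == pytest.approx(0.8)
        assert row["p_fisher"] < 0.05
        assert row["direction"] == "hyper"
        assert (row["start"], row["end"]) == (100, 301)

    def test_spacing_rule_breaks_regions(self):
        a = _pooled([100, 500, 900], [(20, 18)] * 3)
        b = _pooled([100, 500, 900], [(20, 2)] * 3)
        assert len(find_dmrs(a, b, "CG")) == 0

    def test_identical_populations_no_dmrs(self, toy_sites):
        assert len(find_all_dmrs(toy_sites, toy_sites.copy())) == 0

    def test_sign_change_breaks_chain(self):
        a = _pooled([100, 200, 300], [(20, 18), (20, 2), (20, 18)])
        b = _pooled([100, 200, 300], [(20, 2), (20, 18), (20, 2)])
        assert len(find_dmrs(a, b, "CG")) == 0

    def test_coverage_strictly_above_threshold(self):
        # pooled depth exactly 10 must not seed a region ("more than 10")
        a = _pooled([100, 200, 300], [(10, 9)] * 3)
        b = _pooled([100, 200, 300], [(10, 1)] * 3)
        assert len(find_dmrs(a, b, "CG")) == 0

    def test_unknown_context_rejected(self, toy_sites):
        with pytest.raises(ValueError):
            find_dmrs(toy_sites, toy_sites, "CpG")

    def test_population_swap_symmetry(self, small_cohort):
        pa = small_cohort.pooled_table("A")
        pb = small_cohort.pooled_table("B")
        fwd = find_dmrs(pa, pb, "CG").sort_values("start").reset_index(drop=True)
        rev = find_dmrs(pb, pa, "CG").sort_values("start").reset_index(drop=True)
        assert len(fwd) == len(rev)
        assert (fwd["start"] == rev["start"]).all()
        assert (fwd["end"] == rev["end"]).all()
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_fisher"], rev["p_fisher"], rtol=1e-9)
        assert ((fwd["direction"] == "hyper") == (rev["direction"] == "hypo")).all()

    def test_input_order_invariance(self, small_cohort):
        pa = small_cohort.pooled_table("A")
        pb = small_cohort.pooled_table("B")
        ref = find_dmrs(pa, pb, "CHH")
        shuf = find_dmrs(pa.sample(frac=1, random_state=1),
                         pb.sample(frac=1, random_state=2), "CHH")
        pd.testing.assert_frame_equal(
            ref.sort_values("start").reset_index(drop=True),
            shuf.sort_values("start").reset_index(drop=True))

    def test_emitted_dmrs_respect_all_thresholds(self, small_cohort):
        params = DmrParams()
        dmrs = find_all_dmrs(small_cohort.pooled_table("A"),
                             small_cohort.pooled_table("B"), params)
        assert len(dmrs) > 0
        for _, d in dmrs.iterrows():
            assert d["n_sites"] >= params.min_sites
            assert abs(d["delta"]) >= params.min_delta[d["context"]]
            assert d["p_fisher"] < params.alpha
            assert d["end"] > d["start"]


class TestSummary:
    def test_empty_input_all_zero(self):
        s = summarize_dmrs(pd.DataFrame(columns=["chrom", "start", "end",
                                                 "context", "direction"]))
        assert all(v["n"] == 0 for v in s["per_context"].values())

    def test_cross_context_overlap_counted(self):
        dmrs = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [100, 150], "end": [200, 250],
            "context": ["CG", "CHH"], "direction": ["hyper", "hyper"]})
        s = summarize_dmrs(dmrs)
        assert s["overlap"]["CG"]["CHH"] == 1
        assert s["overlap"]["CHH"]["CG"] == 1
        assert s["overlap"]["CG"]["CHG"] == 0
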