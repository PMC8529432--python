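"""Windowed Fst, Tajima's D, pi, DSR calling and DMR integration."""
import numpy as np
import pandas as pd
import pytest

from epidiverge.popgen import (GenotypeTable, call_dsr, dmr_fst_correlation,
                               dsr_genes, nucleotide_diversity, overlap_venn,
                               tajimas_d, window_fst)
from oracles import pi_pairwise, tajima_direct, wc_fst_window


def _gt(pos, dosages, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    samples = [f"A{i}" for i in range(dosages.shape[1] // 2)] + \
              [f"B{i}" for i in range(dosages.shape[1] - dosages.shape[1] // 2)]
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    return GenotypeTable(sites, dosages, samples), {s: s[0] for s in samples}


class TestFst:
    GENOME = {"chr1": 1000}

    def test_fixed_difference_is_one(self):
        gt, pops = _gt([10, 20, 30], [[0, 0, 0, 2, 2, 2]] * 3)
        w = window_fst(gt, pops, self.GENOME, window_bp=1000)
        assert w.loc[0, "fst"] == pytest.approx(1.0)

    def test_equal_frequencies_near_zero_in_expectation(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=2000)
        dos = rng.binomial(2, p[:, None], size=(2000, 10)).astype(np.int8)
        gt, pops = _gt(np.arange(2000), dos)
        w = window_fst(gt, pops, {"chr1": 2000}, window_bp=2000)
        assert abs(w.loc[0, "fst"]) < 0.05

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.1] = -1
        gt, pops = _gt(np.arange(50), dos)
        w = window_fst(gt, pops, {"chr1": 50}, window_bp=50)
        expected = wc_fst_window(dos[:, :5], dos[:, 5:])
        assert w.loc[0, "fst"] == pytest.approx(expected, abs=1e-9)

    def test_population_label_swap_invariant(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        gt, pops = _gt(np.arange(40), dos)
        swapped = {s: ("B" if p == "A" else "A") for s, p in pops.items()}
        w1 = window_fst(gt, pops, {"chr1": 40}, window_bp=40)
        w2 = window_fst(gt, swapped, {"chr1": 40}, window_bp=40)
        assert w1.loc[0, "fst"] == pytest.approx(w2.loc[0, "fst"], rel=1e-12)

    def test_undefined_window_flagged(self):
        gt, pops = _gt([10], [[0, 0, 0, 0, 0, 0]])  # monomorphic
        w = window_fst(gt, pops, {"chr1": 1000}, window_bp=1000)
        assert not w.loc[0, "defined"]
        assert np.isnan(w.loc[0, "fst"])


class TestTajimasD:
    def test_hand_built_window_matches_direct_formula(self):
        # 4 accessions = 8 haplotypes, 5 segregating sites
        dos = np.array([[0, 1, 2, 1],
                        [1, 0, 0, 0],
                        [2, 2, 1, 0],
                        [0, 0, 0, 1],
                        [1, 1, 1, 1]], dtype=np.int8)
        assert tajimas_d(dos) == pytest.approx(tajima_direct(dos), abs=1e-9)

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(np.zeros((5, 4), dtype=np.int8)))

    def test_too_few_haplotypes_undefined(self):
        assert np.isnan(tajimas_d(np.array([[0], [1]], dtype=np.int8)))

    def test_missing_data_drops_sites(self):
        dos = np.array([[0, 1, 2, 1], [1, -1, 0, 0], [2, 2, 1, 0]], dtype=np.int8)
        complete = dos[[0, 2]]
        assert tajimas_d(dos) == pytest.approx(tajima_direct(complete), abs=1e-9)

    def test_sign_tracks_frequency_spectrum(self):
        n_acc = 10
        # singleton-heavy: rare variants -> negative D
        singletons = np.zeros((8, n_acc), dtype=np.int8)
        singletons[:, 0] = 1
        # intermediate-heavy: balanced variants -> positive D
        balanced = np.zeros((8, n_acc), dtype=np.int8)
        balanced[:, : n_acc // 2] = 2
        assert tajimas_d(singletons) < 0 < tajimas_d(balanced)


class TestPi:
    def test_monomorphic_window_zero(self):
        assert nucleotide_diversity(np.zeros((10, 5), dtype=np.int8), 1000) == 0.0

    def test_closed_form_single_snp(self):
        # p = 0.5 with 10 haplotypes over 1 kb
        dos = np.array([[1, 1, 1, 1, 1]], dtype=np.int8)
        expected = (2 * 0.25 * 10 / 9) / 1000
        assert nucleotide_diversity(dos, 1000) == pytest.approx(expected, rel=1e-9)

    def test_matches_pairwise_difference_oracle(self):
        rng = np.random.default_rng(6)
        dos = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.15] = -1
        assert nucleotide_diversity(dos, 500) == pytest.approx(
            pi_pairwise(dos, 500), abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
        assert nucleotide_diversity(dos, 100) >= 0


class TestDsr:
    def _windows(self, fst):
        n = len(fst)
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 1000,
                             "end": (np.arange(n) + 1) * 1000, "fst": fst})

    def test_distinct_values_top_five_percent(self):
        w = self._windows(np.linspace(0, 1, 100))
        assert len(call_dsr(w)) == 5

    def test_ties_at_threshold_included(self):
        fst = np.concatenate([np.zeros(90), np.full(10, 0.8)])
        w = self._windows(fst)
        assert len(call_dsr(w)) == 10

    def test_all_undefined_raises(self):
        w = self._windows(np.full(30, np.nan))
        with pytest.raises(ValueError):
            call_dsr(w)

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError):
            call_dsr(self._windows(np.linspace(0, 1, 10)))

    def test_dsr_genes_overlap(self):
        dsrs = self._windows([0.9]).iloc[:1]
        genes = pd.DataFrame({"gene_id": ["in", "out"], "chrom": "chr1",
                              "start": [500, 5_000], "end": [1_500, 6_000],
                              "strand": "+", "biotype": "mRNA"})
        assert dsr_genes(dsrs, genes) == {"in"}


class TestIntegration:
    def test_proportional_counts_r_one(self):
        w = pd.DataFrame({"fst": np.linspace(0.01, 0.5, 30)})
        w["dmr_count_CG"] = (w["fst"] * 100).round()
        w["dmr_count_CHG"] = 5
        w["dmr_count_CHH"] = (w["fst"] * 40).round()
        out = dmr_fst_correlation(w)
        assert out["CG"]["r"] > 0.99
        assert not out["CHG"]["defined"]  # constant counts

    def test_overlap_venn_counts(self):
        assert overlap_venn({"a", "b"}, {"b", "c", "d"}) == \
            {"only_a": 1, "only_b": 2, "shared": 1}
        assert overlap_venn(set(), {"x"}) == {"only_a": 0, "only_b": 1, "shared": 0}
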