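"""PCA, PC loadings, loading correlations, frequency contrasts, heat maps."""

import numpy as np
import pandas as pd
import pytest

from helpers import make_freq_table, make_panel
from polyadapt import (DriftSpec, compute_pcs, freq_contrast, harmonize,
                       loading_correlations, maf_bin_heatmap, pc_loadings,
                       simulate_frequencies, simulate_genotype_panel)
from polyadapt.stratification import _jackknife_pearson


def two_pop_panel(seed=0, L=600, n=80, fst=0.2):
    spec = DriftSpec(M=2, L=L, F=fst * np.eye(2), seed=seed)
    freqs, _ = simulate_frequencies(spec)
    return simulate_genotype_panel(freqs, n_per_pop=n, seed=seed + 1)


class TestComputePcs:
    def test_pc1_separates_populations(self):
        panel = two_pop_panel()
        pcs = compute_pcs(panel, k=2)
        label = (panel.individuals["population"] == "pop1").astype(float)
        r = np.corrcoef(pcs.scores["PC1"], label)[0, 1]
        assert abs(r) > 0.99

    def test_unstructured_panel_has_no_axis(self):
        spec = DriftSpec(M=1, L=500, F=np.zeros((1, 1)), seed=3)
        freqs, _ = simulate_frequencies(spec)
        panel = simulate_genotype_panel(freqs, n_per_pop=120, seed=4)
        pcs = compute_pcs(panel, k=2)
        halves = np.repeat([0.0, 1.0], 60)
        assert abs(np.corrcoef(pcs.scores["PC1"], halves)[0, 1]) < 0.1

    def test_duplicating_individuals_preserves_directions(self):
        panel = two_pop_panel(seed=5, L=200, n=30)
        dup_counts = pd.concat([panel.counts, panel.counts])
        dup_ind = pd.concat([panel.individuals, panel.individuals])
        dup_ind.index = [f"i{k}" for k in range(len(dup_ind))]
        dup_counts.index = dup_ind.index
        from polyadapt.containers import GenotypePanel
        dup = GenotypePanel(counts=dup_counts, individuals=dup_ind,
                            snps=panel.snps, ploidy=2)
        a = compute_pcs(panel, k=1).scores["PC1"].to_numpy()
        b = compute_pcs(dup, k=1).scores["PC1"].to_numpy()
        n = len(a)
        np.testing.assert_allclose(np.abs(b[:n]), np.abs(b[n:]), atol=1e-8)
        r = np.corrcoef(a, b[:n])[0, 1]
        assert abs(r) > 0.9999

    def test_scores_zero_mean(self):
        pcs = compute_pcs(two_pop_panel(seed=6), k=3)
        assert np.abs(pcs.scores.mean()).max() < 1e-8

    def test_maf_filter_applies(self):
        counts = np.zeros((50, 2))
        counts[:2, 0] = 1            # MAF 0.02 at s1
        counts[:25, 1] = 1           # MAF 0.25 at s2
        pcs = compute_pcs(make_panel(counts), k=1, maf_min=0.05)
        assert list(pcs.snp_ids) == ["s2"]

    def test_k_reduced_to_rank(self, caplog):
        panel = two_pop_panel(seed=7, L=20, n=5)
        with caplog.at_level("WARNING"):
            pcs = compute_pcs(panel, k=15)
        assert pcs.k <= 10


class TestPcLoadings:
    def test_orthogonal_genotype_zero_loading(self):
        rng = np.random.default_rng(8)
        counts = rng.binomial(2, 0.5, size=(40, 4)).astype(float)
        panel = make_panel(counts)            # sex all zero
        pcs = compute_pcs(panel, k=1)
        score = pcs.scores["PC1"].to_numpy()
        # replace s1 with a vector orthogonal to PC1 and the intercept
        v = rng.normal(size=40)
        v -= v.mean()
        v -= v @ score / (score @ score) * score
        v = (v - v.min()) / (v.max() - v.min()) * 2   # into [0, 2]
        # rescaling breaks orthogonality only via the mean shift, which the
        # intercept absorbs; re-project to be exact
        v -= (v - v.mean()) @ score / (score @ score) * score
        g = panel.counts.copy()
        g["s1"] = v
        from polyadapt.containers import GenotypePanel
        panel2 = GenotypePanel(counts=g.clip(0, 2),
                               individuals=panel.individuals,
                               snps=panel.snps, ploidy=2)
        load = pc_loadings(pcs, panel2)
        assert load.loc["s1", "PC1"] == pytest.approx(0.0, abs=1e-8)

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(9)
        counts = rng.binomial(2, 0.5, size=(40, 3)).astype(float)
        panel = make_panel(counts)
        pcs = compute_pcs(panel, k=1)
        pcs.scores["PC1"] = 0.5 * counts[:, 0] - 0.5 * counts[:, 0].mean()
        load = pc_loadings(pcs, panel)
        assert load.loc["s1", "PC1"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_lstsq_oracle_with_sex(self):
        rng = np.random.default_rng(10)
        counts = rng.binomial(2, 0.4, size=(6, 2)).astype(float)
        sex = np.array([0, 1, 0, 1, 0, 1])
        panel = make_panel(counts, sex=sex)
        pcs = compute_pcs(panel, k=1)
        load = pc_loadings(pcs, panel)
        for j, snp in enumerate(["s1", "s2"]):
            X = np.column_stack([np.ones(6), sex, counts[:, j]])
            coef, *_ = np.linalg.lstsq(X, pcs.scores["PC1"].to_numpy(),
                                       rcond=None)
            assert load.loc[snp, "PC1"] == pytest.approx(coef[2], abs=1e-10)

    def test_monomorphic_snp_missing(self):
        counts = np.column_stack([np.ones(30), np.random.default_rng(11)
                                  .binomial(2, 0.5, 30)]).astype(float)
        panel = make_panel(counts)
        pcs = compute_pcs(panel, k=1, maf_min=0.0)
        load = pc_loadings(pcs, panel)
        assert np.isnan(load.loc["s1", "PC1"])


class TestLoadingCorrelations:
    def test_perfect_correlation_flagged(self):
        rng = np.random.default_rng(12)
        loadings = pd.DataFrame(
            rng.normal(size=(2000, 3)), columns=["PC1", "PC2", "PC3"],
            index=[f"s{i}" for i in range(2000)])
        v = 2.5 * loadings["PC1"]
        out = loading_correlations(v, loadings, n_jackknife=100, n_pcs=3)
        assert out.loc["PC1", "r"] == pytest.approx(1.0)
        assert out.loc["PC1", "bonferroni"]

    def test_null_correlations_small_and_unflagged(self):
        flags = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            loadings = pd.DataFrame(
                rng.normal(size=(50_000, 5)),
                columns=[f"PC{k+1}" for k in range(5)],
                index=[f"s{i}" for i in range(50_000)])
            v = pd.Series(rng.normal(size=50_000), index=loadings.index)
            out = loading_correlations(v, loadings, n_jackknife=1000,
                                       n_pcs=5)
            assert (out["r"].abs() < 0.02).all()
            flags += int(out["bonferroni"].any())
        assert flags <= 0.05 * reps + 1

    def test_jackknife_se_close_to_analytic(self):
        rng = np.random.default_rng(13)
        n = 20_000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, se = _jackknife_pearson(x, y, 1000)
        analytic = 1.0 / np.sqrt(n - 3)
        assert se < 1.5 * analytic
        assert se > analytic / 1.5

    def test_block_reduction_warning(self, caplog):
        rng = np.random.default_rng(14)
        loadings = pd.DataFrame(rng.normal(size=(50, 1)), columns=["PC1"],
                                index=[f"s{i}" for i in range(50)])
        v = pd.Series(rng.normal(size=50), index=loadings.index)
        with caplog.at_level("WARNING"):
            loading_correlations(v, loadings, n_jackknife=1000, n_pcs=1)
        assert "B reduced" in caplog.text


class TestFreqContrast:
    def ss(self, betas):
        n = len(betas)
        return pd.DataFrame({
            "snp": [f"s{i+1}" for i in range(n)], "chrom": "1",
            "pos": (np.arange(n) + 1) * 1000, "a1": "A", "a2": "G",
            "beta": betas, "se": 0.05, "p": 0.5, "freq_a1": 0.5,
        })

    def test_signs(self):
        fa = pd.Series([0.6, 0.6], index=["s1", "s2"])
        fb = pd.Series([0.4, 0.4], index=["s1", "s2"])
        delta = freq_contrast(fa, fb, self.ss([0.1, -0.1]))
        assert delta["s1"] == pytest.approx(0.2)
        assert delta["s2"] == pytest.approx(-0.2)

    def test_zero_beta_dropped(self):
        fa = pd.Series([0.6], index=["s1"])
        fb = pd.Series([0.4], index=["s1"])
        assert len(freq_contrast(fa, fb, self.ss([0.0]))) == 0

    def test_allele_flip_invariance_via_harmonize(self):
        """Flipping A1/A2 labels (and signs) in the input summary stats
        leaves the harmonized contrast unchanged."""
        target = make_freq_table([[0.6, 0.4]], populations=["A", "B"])
        ss = self.ss([0.1])
        flipped = ss.copy()
        flipped[["a1", "a2"]] = [["G", "A"]]
        flipped["beta"] = -flipped["beta"]
        flipped["freq_a1"] = 1 - flipped["freq_a1"]
        h1, _ = harmonize(ss, target)
        h2, _ = harmonize(flipped, target)
        d1 = freq_contrast(target.freq["A"], target.freq["B"], h1)
        d2 = freq_contrast(target.freq["A"], target.freq["B"], h2)
        pd.testing.assert_series_equal(d1, d2)


class TestHeatmap:
    def test_constant_value_everywhere(self):
        rng = np.random.default_rng(15)
        idx = [f"s{i}" for i in range(5000)]
        fa = pd.Series(rng.uniform(0.01, 0.99, 5000), index=idx)
        fb = pd.Series(rng.uniform(0.01, 0.99, 5000), index=idx)
        v = pd.Series(0.1, index=idx)
        hm = maf_bin_heatmap(v, fa, fb, min_count=10)
        shown = hm.mean[~hm.mask]
        np.testing.assert_allclose(shown, 0.1)

    def test_count_threshold_boundary(self):
        def build(count):
            idx = [f"s{i}" for i in range(count)]
            fa = pd.Series(0.12, index=idx)
            fb = pd.Series(0.12, index=idx)
            v = pd.Series(1.0, index=idx)
            return maf_bin_heatmap(v, fa, fb, min_count=300)
        assert build(299).mask[2, 2]
        assert not build(300).mask[2, 2]

    def test_antisymmetric_construction(self):
        rng = np.random.default_rng(16)
        idx = [f"s{i}" for i in range(40_000)]
        fa = pd.Series(rng.uniform(0.0, 0.5, 40_000), index=idx)
        fb = pd.Series(rng.uniform(0.0, 0.5, 40_000), index=idx)
        v = fa - fb     # value = MAF_A − MAF_B since freq < 0.5
        hm = maf_bin_heatmap(v, fa, fb, min_count=50)
        ok = ~hm.mask & ~hm.mask.T
        np.testing.assert_allclose(hm.mean.T[ok], -hm.mean[ok], atol=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            maf_bin_heatmap(pd.Series(dtype=float), pd.Series(dtype=float),
                            pd.Series(dtype=float))
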