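"""LD-block ascertainment, genotypic r², clumping and pruning."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_clump, brute_prune
from helpers import make_panel
from polyadapt import (ClumpSpec, clump, genotypic_r2, lowest_p_per_block,
                       prune, read_ld_blocks)
from polyadapt.ldselect import assign_blocks


def sumstats_at(ids, pos, p, chrom="1"):
    return pd.DataFrame({
        "snp": ids, "chrom": chrom, "pos": pos, "a1": "A", "a2": "G",
        "beta": 0.1, "se": 0.05, "p": p, "freq_a1": 0.5,
    })


class TestBlocks:
    def test_read_converts_and_validates(self, tmp_path):
        path = tmp_path / "blocks.bed"
        path.write_text("chr1\t0\t100\n1\t100\t200\n2\t50\t150\n")
        blocks = read_ld_blocks(path)
        assert len(blocks) == 3
        ss = sumstats_at(["a", "b", "c"], [100, 101, 250], [0.1, 0.2, 0.3])
        # 1-based pos 100 -> 0-based 99 -> first block [0, 100)
        assert assign_blocks(ss, blocks).tolist()[:2] == [0, 1]
        assert assign_blocks(ss, blocks).tolist()[2] == -1

    def test_overlapping_blocks_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t0\t100\n1\t50\t150\n")
        with pytest.raises(ValueError, match="overlap"):
            read_ld_blocks(path)

    def test_lowest_p_picks_argmin(self, tmp_path):
        path = tmp_path / "blocks.bed"
        path.write_text("1\t0\t1000\n1\t1000\t2000\n")
        ss = sumstats_at(["a", "b", "c", "d"], [10, 20, 30, 1500],
                         [0.5, 0.01, 0.2, 0.9])
        assert lowest_p_per_block(ss, read_ld_blocks(path)) == ["b", "d"]

    def test_tie_break_lower_position(self, tmp_path):
        path = tmp_path / "blocks.bed"
        path.write_text("1\t0\t1000\n")
        ss = sumstats_at(["late", "early"], [500, 100], [1e-6, 1e-6])
        picked = lowest_p_per_block(ss, read_ld_blocks(path))
        # brute force: among minimal-P SNPs, the lowest position wins
        sub = ss[ss["p"] == ss["p"].min()]
        expect = sub.sort_values(["pos", "snp"]).iloc[0]["snp"]
        assert picked == [expect] == ["early"]


class TestGenotypicR2:
    def test_self_is_one(self):
        panel = make_panel([[0], [1], [2], [1]])
        assert genotypic_r2(panel, "s1", "s1") == pytest.approx(1.0)

    def test_orthogonal_counts(self):
        panel = make_panel([[0, 0], [0, 2], [2, 0], [2, 2]])
        assert genotypic_r2(panel, "s1", "s2") == pytest.approx(0.0)

    def test_perfect_anticorrelation(self):
        panel = make_panel([[0, 2], [1, 1], [1, 1], [2, 0]])
        assert genotypic_r2(panel, "s1", "s2") == pytest.approx(1.0)

    def test_monomorphic_is_zero_with_warning(self, caplog):
        panel = make_panel([[1, 0], [1, 2], [1, 1]])
        with caplog.at_level("WARNING"):
            assert genotypic_r2(panel, "s1", "s2") == 0.0
        assert "zero genotype variance" in caplog.text


def correlated_pair(rng, n, rho):
    """Two count vectors with genotypic correlation ≈ rho."""
    a = rng.binomial(2, 0.5, n).astype(float)
    b = np.where(rng.uniform(size=n) < abs(rho), a, rng.binomial(2, 0.5, n))
    return a, b


class TestClump:
    def toy_panel_and_ss(self):
        rng = np.random.default_rng(42)
        n = 200
        g1, g2 = correlated_pair(rng, n, 0.75)       # r2 ~ 0.5
        g3, g4 = correlated_pair(rng, n, 0.95)       # r2 ~ 0.9
        g5 = rng.binomial(2, 0.5, n).astype(float)
        counts = np.column_stack([g1, g2, g3, g4, g5])
        pos = [100_000, 200_000, 5_000_000, 5_100_000, 9_000_000]
        panel = make_panel(counts, pos=pos)
        ss = sumstats_at(["s1", "s2", "s3", "s4", "s5"], pos,
                         [1e-10, 1e-9, 1e-6, 0.2, 1e-3])
        return panel, ss

    def test_five_snp_toy(self):
        panel, ss = self.toy_panel_and_ss()
        spec = ClumpSpec(p1=0.01, p2=1.0, r2=0.1, window=1_000_000)
        assert clump(ss, panel, spec) == ["s1", "s3", "s5"]
        # cross-check against the brute-force reference
        ids = ss["snp"].tolist()
        r2 = {frozenset((a, b)): genotypic_r2(panel, a, b)
              for i, a in enumerate(ids) for b in ids[i + 1:]}
        snps = [{"id": r["snp"], "chrom": r["chrom"], "pos": r["pos"],
                 "p": r["p"]} for r in ss.to_dict("records")]
        assert clump(ss, panel, spec) == brute_clump(
            snps, r2, spec.p1, spec.p2, spec.r2, spec.window)

    def test_no_ld_every_significant_snp_is_index(self):
        rng = np.random.default_rng(0)
        counts = rng.binomial(2, 0.5, size=(500, 6)).astype(float)
        pos = (np.arange(6) + 1) * 10_000_000   # all out of window
        panel = make_panel(counts, pos=pos)
        ss = sumstats_at([f"s{i+1}" for i in range(6)], pos,
                         [1e-5, 0.5, 1e-3, 0.9, 1e-4, 2e-3])
        spec = ClumpSpec(p1=0.01, p2=1.0, r2=0.1, window=1_000_000)
        assert set(clump(ss, panel, spec)) == {"s1", "s3", "s5", "s6"}

    def test_window_excludes_distant_ld(self):
        rng = np.random.default_rng(1)
        g1, g2 = correlated_pair(rng, 300, 0.75)
        panel = make_panel(np.column_stack([g1, g2]),
                           pos=[1_000_000, 3_000_000])
        ss = sumstats_at(["s1", "s2"], [1_000_000, 3_000_000], [1e-8, 1e-6])
        spec = ClumpSpec(p1=0.01, p2=1.0, r2=0.1, window=1_000_000)
        assert clump(ss, panel, spec) == ["s1", "s2"]

    def test_empty_candidate_set_warns(self, caplog):
        panel, ss = self.toy_panel_and_ss()
        spec = ClumpSpec(p1=1e-20, p2=1.0, r2=0.1, window=1_000_000)
        with caplog.at_level("WARNING"):
            assert clump(ss, panel, spec) == []

    def test_index_set_consistency_with_p2_one(self):
        """Clumping with p1=1 then filtering indices at p1' equals clumping
        at p1' directly (greedy consistency)."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n_snp = int(rng.integers(4, 10))
            counts = rng.binomial(2, rng.uniform(0.2, 0.8, n_snp),
                                  size=(150, n_snp)).astype(float)
            pos = np.sort(rng.choice(np.arange(1, 3_000_000, 1000), n_snp,
                                     replace=False))
            ids = [f"s{i+1}" for i in range(n_snp)]
            ss = sumstats_at(ids, pos, rng.uniform(1e-6, 1, n_snp))
            panel = make_panel(counts, pos=pos)
            wide = ClumpSpec(p1=1.0, p2=1.0, r2=0.2, window=500_000)
            tight = ClumpSpec(p1=0.05, p2=1.0, r2=0.2, window=500_000)
            wide_idx = [s for s in clump(ss, panel, wide)
                        if ss.set_index("snp").loc[s, "p"] < tight.p1]
            assert wide_idx == clump(ss, panel, tight)


class TestPrune:
    def test_unlinked_all_retained(self):
        rng = np.random.default_rng(2)
        counts = rng.binomial(2, 0.5, size=(400, 5)).astype(float)
        panel = make_panel(counts, pos=(np.arange(5) + 1) * 10_000_000)
        assert prune(panel, 0.2, 1_000_000) == [f"s{i+1}" for i in range(5)]

    def test_linked_pair_keeps_earlier(self):
        rng = np.random.default_rng(3)
        g1, g2 = correlated_pair(rng, 400, 0.95)
        panel = make_panel(np.column_stack([g1, g2]), pos=[100, 50_000])
        assert prune(panel, 0.2, 1_000_000) == ["s1"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(30):
            n_snp = int(rng.integers(3, 11))
            counts = np.column_stack([
                rng.binomial(2, rng.uniform(0.2, 0.8), 120).astype(float)
                for _ in range(n_snp)])
            pos = np.sort(rng.choice(np.arange(1, 2_000_000, 997), n_snp,
                                     replace=False))
            ids = [f"s{i+1}" for i in range(n_snp)]
            panel = make_panel(counts, pos=pos, ids=ids)
            r2 = {frozenset((a, b)): genotypic_r2(panel, a, b)
                  for i, a in enumerate(ids) for b in ids[i + 1:]}
            snps = [{"id": s, "chrom": "1", "pos": p}
                    for s, p in zip(ids, pos)]
            assert prune(panel, 0.3, 400_000) == brute_prune(
                snps, r2, 0.3, 400_000)
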