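import numpy as np
import pandas as pd
import pytest

from hapblockscan.blocks import (aggregate_summary, block_summary,
                                 clustering_rate, four_gamete_blocks,
                                 gabriel_blocks, select_top_blocks)
from hapblockscan.regions import HaploBlock, overlap_bp
from hapblockscan.simdata import PopulationConfig, SimConfig, simulate_panel

from conftest import make_panel


def planted_config(seed):
    return SimConfig(seed=seed, populations=[PopulationConfig("P", 25, 12, 100)],
                     chrom_lengths={"1": 200_000}, site_density=0.8,
                     recomb_rate=5e-6, n_generations=50,
                     planted_block_regions={"1": [(60_000, 150_000)]})


class TestFourGameteBlocks:
    def test_three_gametes_stay_in_one_block(self):
        # columns show gametes AB, Ab, aB only
        hap = np.array([[1, 1], [1, 0], [0, 1], [1, 1]] * 5)
        panel = make_panel(hap, [100, 500])
        blocks = four_gamete_blocks(panel, "1")
        assert len(blocks) == 1
        assert blocks[0].snp_indices == [0, 1]

    def test_four_gametes_split_blocks(self):
        hap = np.array([[1, 1], [1, 0], [0, 1], [0, 0]] * 5)
        panel = make_panel(hap, [100, 500])
        assert four_gamete_blocks(panel, "1") == []  # two singletons, no block

    def test_rare_fourth_gamete_below_threshold_ignored(self):
        # 4th gamete (0,0) appears once among 200 haplotypes: freq 0.005
        hap = np.array([[1, 1], [1, 0], [0, 1], [1, 1]] * 50, dtype=np.int8)
        hap[3] = [0, 0]
        panel = make_panel(hap, [100, 500])
        blocks = four_gamete_blocks(panel, "1", min_hap_freq=0.01)
        assert len(blocks) == 1

    def test_planted_region_recovered_as_single_block(self):
        panel, _ = simulate_panel(planted_config(123))
        a, b = 60_000, 150_000
        blocks = four_gamete_blocks(panel, "1")
        best = max(overlap_bp(bl.start, bl.end, a, b) for bl in blocks)
        assert best >= 0.9 * (b - a + 1)


class TestGabrielBlocks:
    def test_planted_segment_single_block(self):
        panel, _ = simulate_panel(planted_config(7))
        a, b = 60_000, 150_000
        blocks = gabriel_blocks(panel, "1")
        best = max(overlap_bp(bl.start, bl.end, a, b) for bl in blocks)
        assert best >= 0.9 * (b - a + 1)

    def test_two_segments_separated_by_free_recombination(self):
        """Two independent strong-LD segments with an uncorrelated spacer
        never merge into one block."""
        rng = np.random.default_rng(42)
        n_hap = 100
        left = rng.integers(0, 2, n_hap)
        right = rng.integers(0, 2, n_hap)
        spacer = rng.integers(0, 2, (n_hap, 2))
        hap = np.column_stack([left, left, left, spacer, right, right, right])
        panel = make_panel(hap, [1000, 2000, 3000, 10_000, 11_000,
                                 20_000, 21_000, 22_000])
        blocks = gabriel_blocks(panel, "1")
        assert len(blocks) >= 2
        for bl in blocks:
            assert not (bl.start <= 3000 and bl.end >= 20_000)

    def test_blocks_never_exceed_max_span(self, sim_panel):
        for bl in gabriel_blocks(sim_panel, "1", max_span_kb=50.0):
            assert bl.length_bp <= 50_000

    def test_accepted_blocks_do_not_overlap(self, sim_panel):
        blocks = gabriel_blocks(sim_panel, "1")
        for x, y in zip(blocks, blocks[1:]):
            assert x.end < y.start
        for bl in blocks:
            assert bl.n_snps >= 2


class TestBlockSummary:
    def test_printed_row_arithmetic(self):
        """Aggregation reproduces mean block size from count and total length."""
        per_chrom = pd.DataFrame([
            {"chrom": "1", "n_blocks": 2336, "total_length_kb": 43176.07,
             "min_kb": 0.002, "max_kb": 199.95, "n_snps_in_blocks": 10587,
             "min_snps": 2, "max_snps": 44},
            {"chrom": "2", "n_blocks": 1908, "total_length_kb": 28761.04,
             "min_kb": 0.002, "max_kb": 199.56, "n_snps_in_blocks": 9326,
             "min_snps": 2, "max_snps": 52},
        ])
        out = aggregate_summary(per_chrom)
        assert out.loc[0, "mean_kb"] == pytest.approx(18.48, abs=0.005)
        assert out.loc[0, "mean_snps"] == pytest.approx(4.53, abs=0.005)

    def test_summary_from_blocks_matches_hand_computation(self):
        hap = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 1, 1], [0, 0, 0, 0]])
        panel = make_panel(hap, [100, 200, 5000, 9000])
        blocks = [HaploBlock("1", 100, 200, [0, 1]),
                  HaploBlock("1", 5000, 9000, [2, 3])]
        out = block_summary(blocks, panel)
        row = out[out["chrom"] == "1"].iloc[0]
        assert row["n_blocks"] == 2
        assert row["total_length_kb"] == pytest.approx(0.101 + 4.001)
        assert row["n_snps_in_blocks"] == 4
        total = out[out["chrom"] == "Total"].iloc[0]
        assert total["pct_snps_in_blocks"] == pytest.approx(100.0)

    def test_two_adjacent_snps_is_two_bp(self):
        block = HaploBlock("1", 1_936_544, 1_936_545, [0, 1])
        assert block.length_bp == 2
        assert block.length_kb == pytest.approx(0.002)

    def test_chromosome_without_blocks_gets_zero_row(self):
        hap = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        panel = make_panel(hap, [100, 200])
        panel.sites.loc[1, "chrom"] = "2"
        panel.sites.loc[1, "pos"] = 100
        out = block_summary([], panel)
        assert (out[out["chrom"] != "Total"]["n_blocks"] == 0).all()

    def test_clustering_rate(self):
        assert clustering_rate(50, 200) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            clustering_rate(1, 0)


class TestSelectTopBlocks:
    @staticmethod
    def _mk(start, length, n_snps, chrom="1"):
        return HaploBlock(chrom, start, start + length - 1,
                          list(range(n_snps)) if n_snps >= 2 else [])

    def test_fewer_than_k_returns_all(self):
        blocks = [self._mk(i * 10_000, 100 + i, 2 + i) for i in range(5)]
        assert len(select_top_blocks(blocks, 10, 10)) == 5

    def test_block_top_in_both_appears_once_with_flags(self):
        big = self._mk(1, 10_000, 50)
        others = [self._mk(20_000 + i * 5000, 100 + i, 2) for i in range(4)]
        out = select_top_blocks([big] + others, k_length=1, k_snps=1)
        flagged = [s for s in out if s.block is big]
        assert len(flagged) == 1
        assert flagged[0].by_length and flagged[0].by_snps
        assert len(out) == 1

    def test_known_ranks_exact_selection(self):
        lengths = [500, 400, 300, 200, 100]
        snps = [2, 3, 9, 5, 7]
        blocks = [self._mk(1 + i * 10_000, lengths[i], snps[i])
                  for i in range(5)]
        out = select_top_blocks(blocks, k_length=2, k_snps=2)
        by_len = {s.block.start for s in out if s.by_length}
        by_snp = {s.block.start for s in out if s.by_snps}
        assert by_len == {1, 10_001}          # lengths 500, 400
        assert by_snp == {20_001, 40_001}     # snp counts 9, 7
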