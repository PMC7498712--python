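import numpy as np
import pytest

from hapblockscan.diversity import (block_spectrum, breed_block_summary,
                                    fst_two_populations, haplotype_diversity,
                                    ibs_distance, pairwise_fst)
from hapblockscan.io import split_by_population
from hapblockscan.regions import HaploBlock
from hapblockscan.simdata import PopulationConfig, SimConfig, simulate_panel

from conftest import make_panel


def wc_fst_scalar(g1, g2):
    """Textbook per-locus Weir & Cockerham (1984) theta, ratio of sums."""
    num = den = 0.0
    r = 2
    n1, n2 = g1.shape[0], g2.shape[0]
    for l in range(g1.shape[1]):
        p1 = g1[:, l].sum() / (2 * n1)
        p2 = g2[:, l].sum() / (2 * n2)
        h1 = np.mean(g1[:, l] == 1)
        h2 = np.mean(g2[:, l] == 1)
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1)
                         * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


class TestBlockSpectrum:
    def test_single_haplotype(self):
        hap = np.tile([0, 1], (6, 1))
        panel = make_panel(hap, [100, 200])
        s = block_spectrum(panel, HaploBlock("1", 100, 200, [0, 1]))
        assert s.k == 1
        np.testing.assert_allclose(s.hap_freqs, [1.0])

    def test_two_haplotypes_even(self):
        hap = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        panel = make_panel(hap, [100, 200])
        s = block_spectrum(panel, HaploBlock("1", 100, 200, [0, 1]))
        assert s.k == 2
        np.testing.assert_allclose(s.hap_freqs, [0.5, 0.5])

    def test_matches_string_tally_oracle(self, sim_panel):
        idx = list(range(5))
        block = HaploBlock("1", int(sim_panel.sites.iloc[0]["pos"]),
                           int(sim_panel.sites.iloc[4]["pos"]), idx)
        s = block_spectrum(sim_panel, block)
        strings = ["".join(map(str, row)) for row in sim_panel.haplotypes[:, idx]]
        from collections import Counter

        counts = sorted(Counter(strings).values(), reverse=True)
        np.testing.assert_allclose(
            s.hap_freqs, np.array(counts) / len(strings), atol=1e-12)


class TestHaplotypeDiversity:
    @pytest.mark.parametrize("freqs,expected", [
        ([1.0], 0.0),
        ([0.5, 0.5], 0.5),
        ([0.25] * 4, 0.75),
    ])
    def test_known_spectra(self, freqs, expected):
        s = type("S", (), {"hap_freqs": np.array(freqs)})()
        assert haplotype_diversity(s) == pytest.approx(expected)

    def test_bounded_by_equifrequent_maximum(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 10))
            f = rng.dirichlet(np.ones(k))
            s = type("S", (), {"hap_freqs": f})()
            assert 0.0 <= haplotype_diversity(s) <= 1.0 - 1.0 / k + 1e-12


class TestBreedBlockSummary:
    def test_equifrequent_blocks(self):
        spectra = [type("S", (), {"hap_freqs": np.array([0.25] * 4), "k": 4})()
                   for _ in range(3)]
        freq, div = breed_block_summary(spectra)
        assert freq == pytest.approx(0.25)
        assert div == pytest.approx(0.75)

    def test_monomorphic_block(self):
        s = type("S", (), {"hap_freqs": np.array([1.0]), "k": 1})()
        assert breed_block_summary([s]) == (1.0, 0.0)

    def test_mixed_fixture_matches_brute_force(self):
        specs = [np.array([0.5, 0.5]), np.array([0.7, 0.2, 0.1]),
                 np.array([1.0])]
        spectra = [type("S", (), {"hap_freqs": f, "k": len(f)})() for f in specs]
        freq, div = breed_block_summary(spectra)
        assert freq == pytest.approx(np.mean([1 / 2, 1 / 3, 1]))
        assert div == pytest.approx(np.mean([1 - np.sum(f ** 2) for f in specs]))


class TestIbsDistance:
    def test_identical_individuals_distance_zero(self):
        hap = np.array([[1, 0, 1], [0, 1, 1]] * 2)
        panel = make_panel(hap, [10, 20, 30])
        d = ibs_distance(panel)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        # 4 loci: ibs2 at 2 loci, ibs1 at 1, ibs0 at 1 -> Dst = 0.625
        g1 = [2, 1, 2, 0]
        g2 = [2, 1, 1, 2]
        hap = np.array([
            [1, 1, 1, 0], [1, 0, 1, 0],   # individual 1
            [1, 1, 1, 1], [1, 0, 0, 1],   # individual 2
        ])
        panel = make_panel(hap, [10, 20, 30, 40])
        assert panel.genotypes()[0].tolist() == g1
        assert panel.genotypes()[1].tolist() == g2
        d = ibs_distance(panel)
        assert d.iloc[0, 1] == pytest.approx(1 - 0.625)

    def test_opposite_homozygotes_maximal_distance(self):
        hap = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        panel = make_panel(hap, [10, 20])
        d = ibs_distance(panel)
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self, sim_panel):
        d = ibs_distance(sim_panel)
        np.testing.assert_allclose(d.values, d.values.T)
        np.testing.assert_allclose(np.diag(d.values), 0.0)
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestFst:
    def test_panmictic_split_near_zero(self):
        cfg = SimConfig(seed=31, populations=[PopulationConfig("P", 60, 10, 80)],
                        chrom_lengths={"1": 1_000_000}, site_density=0.5,
                        recomb_rate=1e-6, n_generations=50)
        panel, _ = simulate_panel(cfg)
        g = panel.genotypes()
        assert g.shape[1] >= 200
        fst = fst_two_populations(g[:30], g[30:])
        assert abs(fst) < 0.02

    def test_complete_fixation_gives_one(self):
        g1 = np.full((10, 20), 0)
        g2 = np.full((10, 20), 2)
        assert fst_two_populations(g1, g2) == pytest.approx(1.0)

    def test_matches_scalar_textbook_implementation(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(5, 20, size=2)
            g1 = rng.integers(0, 3, size=(n1, 12))
            g2 = rng.integers(0, 3, size=(n2, 12))
            # keep only loci polymorphic overall
            p = np.vstack([g1, g2]).mean(axis=0)
            keep = (p > 0) & (p < 2)
            if keep.sum() < 2:
                continue
            g1k, g2k = g1[:, keep], g2[:, keep]
            assert fst_two_populations(g1k, g2k) == pytest.approx(
                wc_fst_scalar(g1k, g2k), abs=1e-10)

    def test_divergent_founder_pools_exceed_panmixia(self):
        exceed = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed,
                            populations=[PopulationConfig("A", 15, 8, 50),
                                         PopulationConfig("B", 15, 8, 50)],
                            chrom_lengths={"1": 150_000}, site_density=0.5,
                            recomb_rate=1e-6, n_generations=30)
            panel, _ = simulate_panel(cfg)
            pops = split_by_population(panel)
            fst = pairwise_fst(pops).iloc[0, 1]
            # panmictic comparison: random split of population A
            ga = pops["A"].genotypes()
            null = abs(fst_two_populations(ga[:7], ga[7:]))
            exceed += fst > null
        assert exceed >= int(0.9 * n_seeds)

    def test_matrix_symmetry(self):
        cfg = SimConfig(seed=77,
                        populations=[PopulationConfig(p, 10, 8, 40)
                                     for p in "ABC"],
                        chrom_lengths={"1": 120_000}, site_density=0.5,
                        recomb_rate=1e-6, n_generations=30)
        panel, _ = simulate_panel(cfg)
        mat = pairwise_fst(split_by_population(panel))
        np.testing.assert_allclose(mat.values, mat.values.T)
        np.testing.assert_allclose(np.diag(mat.values), 0.0)
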