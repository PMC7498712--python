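import numpy as np
import pandas as pd
import pytest

from hapblockscan.panel import GenotypePanel, compute_maf


def make_panel(haplotypes, positions, chrom="1", sample_ids=None, pops=None):
    """Build a panel from a (n_hap, n_sites) 0/1 matrix and positions."""
    hap = np.asarray(haplotypes, dtype=np.int8)
    n_ind = hap.shape[0] // 2
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_ind)]
    sites = pd.DataFrame({
        "chrom": [chrom] * hap.shape[1],
        "pos": list(positions),
        "ref": ["A"] * hap.shape[1],
        "alt": ["G"] * hap.shape[1],
        "maf": compute_maf(hap),
    })
    return GenotypePanel(sites, hap, sample_ids, dict(pops or {}))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_panel():
    """4 individuals, 5 sites; columns engineered for LD checks."""
    hap = np.array([
        [1, 1, 0, 1, 0],
        [1, 1, 0, 0, 1],
        [0, 0, 1, 1, 0],
        [0, 0, 1, 0, 1],
        [1, 1, 0, 1, 1],
        [0, 0, 1, 0, 0],
        [1, 1, 0, 1, 0],
        [0, 0, 1, 0, 1],
    ])
    return make_panel(hap, [1000, 2000, 3500, 6000, 9000])


@pytest.fixture(scope="session")
def sim_panel():
    """Moderate single-population simulated panel shared across tests."""
    from hapblockscan.simdata import PopulationConfig, SimConfig, simulate_panel

    cfg = SimConfig(seed=99, populations=[PopulationConfig("P", 30, 10, 80)],
                    chrom_lengths={"1": 400_000}, site_density=0.5,
                    recomb_rate=1e-6, n_generations=60)
    panel, truth = simulate_panel(cfg)
    return panel
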