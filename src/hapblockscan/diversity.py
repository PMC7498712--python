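"""Haplotype diversity, IBS genetic distance and pairwise Fst.

Haplotype diversity within a block is 1 - sum(f_i^2) over the
frequencies of the distinct haplotype strings spanning the block's
SNPs.  Individual-level genetic distance is 1 - Dst, where
Dst = (IBS2 + 0.5 * IBS1) / N is the average proportion of alleles
shared identical by state.  Population differentiation uses the
Weir & Cockerham (1984) ratio-of-sums Fst estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .regions import HaploBlock


@dataclass
class BlockSpectrum:
    block: HaploBlock
    hap_freqs: np.ndarray  # frequencies of distinct haplotype strings, desc.

    @property
    def k(self) -> int:
        return len(self.hap_freqs)


def block_spectrum(panel: GenotypePanel, block: HaploBlock) -> BlockSpectrum:
    """Frequencies of the distinct haplotypes over a block's member SNPs."""
    sub = panel.haplotypes[:, block.snp_indices]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    freqs = np.sort(counts / sub.shape[0])[::-1]
    return BlockSpectrum(block, freqs)


def haplotype_diversity(spectrum: BlockSpectrum) -> float:
    """1 - sum(f_i^2); zero for a monomorphic block."""
    return float(1.0 - np.sum(spectrum.hap_freqs ** 2))


def breed_block_summary(spectra: list[BlockSpectrum]) -> tuple[float, float]:
    """Population-level (mean haplotype frequency, mean diversity).

    The mean haplotype frequency of a block with k distinct haplotypes
    is 1/k; both statistics are unweighted means over blocks.
    """
    if not spectra:
        raise ValueError("need at least one block spectrum")
    mean_freq = float(np.mean([1.0 / s.k for s in spectra]))
    mean_div = float(np.mean([haplotype_diversity(s) for s in spectra]))
    return mean_freq, mean_div


def ibs_distance(panel: GenotypePanel) -> pd.DataFrame:
    """Pairwise genetic distance 1 - Dst between individuals.

    Dst = (IBS2 + 0.5*IBS1)/N over all loci, where a genotype pair
    shares 2, 1 or 0 alleles identical by state.  Returns a symmetric
    DataFrame with zero diagonal, indexed by sample id.
    """
    if panel.n_individuals < 2 or panel.n_sites < 1:
        raise ValueError("need >= 2 individuals and >= 1 locus")
    g = panel.genotypes().astype(np.int16)
    n_ind, n_loci = g.shape
    dist = np.zeros((n_ind, n_ind))
    for i in range(n_ind):
        shared = 2 - np.abs(g[i] - g[i + 1:])  # 2, 1 or 0 alleles IBS
        dst = shared.sum(axis=1) / (2.0 * n_loci)
        dist[i, i + 1:] = 1.0 - dst
        dist[i + 1:, i] = 1.0 - dst
    return pd.DataFrame(dist, index=panel.sample_ids, columns=panel.sample_ids)


def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham a and (a+b+c) components for two samples.

    ``g1``/``g2`` are ALT-dosage genotype matrices (individuals x loci).
    """
    r = 2.0
    n1, n2 = float(g1.shape[0]), float(g2.shape[0])
    p1 = g1.mean(axis=0) / 2.0
    p2 = g2.mean(axis=0) / 2.0
    h1 = (g1 == 1).mean(axis=0)
    h2 = (g2 == 1).mean(axis=0)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
                       / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1.0) / r * s2
                                 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, a + b + c


def fst_two_populations(g1: np.ndarray, g2: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham theta for two genotype matrices."""
    a, abc = _wc_components(g1, g2)
    poly = abc != 0
    if not poly.any():
        raise ValueError("no shared polymorphic sites")
    return float(a[poly].sum() / abc[poly].sum())


def pairwise_fst(panels: dict[str, GenotypePanel]) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir-Cockerham Fst between populations.

    Panels must be restricted to shared sites (same site table).
    """
    pops = list(panels)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    n_sites = {panels[p].n_sites for p in pops}
    if len(n_sites) > 1:
        raise ValueError("panels must be restricted to a shared site set "
                         "(split before per-population MAF filtering)")
    genos = {p: panels[p].genotypes() for p in pops}
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            f = fst_two_populations(genos[p], genos[q])
            mat.loc[p, q] = mat.loc[q, p] = f
    return mat


def write_matrix(mat: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# square matrix; first row/column are labels\n")
        mat.to_csv(fh, sep="\t")
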