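"""Synthetic multi-population SNP panels with known truth.

Haplotypes are produced by a founder-copying model: each population
starts from a small set of founder haplotypes generated under a perfect
phylogeny (infinite-sites mutations on a random founder genealogy, so a
recombination-free genome is four-gamete consistent), tiled into a
Wright-Fisher population of ``2 * ne_true`` haplotype slots.  Each
generation every haplotype is a recombinant mosaic of two random
parents, with crossovers at ``recomb_rate`` per bp — forced to zero
inside planted block regions — which drives r2 toward the
drift-recombination expectation 1/(1 + 4*Ne*c).  Individuals are
sampled after ``n_generations`` rounds, alleles are optionally flipped
at ``mutation_rate``, and sites with panel-wide MAF below 0.05 are
dropped, mirroring the post-filter panels the analysis operates on.

Default study conditions: four populations of 20 diploid individuals,
two chromosomes of a few Mb, effective sizes of order 100, and a
per-bp recombination rate of 1e-8 (1 cM/Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, compute_maf
from .regions import GeneRecord, QtlRecord


@dataclass(frozen=True)
class PopulationConfig:
    label: str
    n_individuals: int
    n_founders: int = 8
    ne_true: int = 100


@dataclass
class SimConfig:
    seed: int
    populations: list[PopulationConfig]
    chrom_lengths: dict[str, int]
    site_density: float = 0.5          # expected SNPs per kb
    recomb_rate: float = 1e-8          # per bp per meiosis
    mutation_rate: float = 0.0         # per-site per-haplotype flip prob
    planted_block_regions: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)          # chrom -> [(start, end)], 1-based
    n_generations: int = 100
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        for chrom, regions in self.planted_block_regions.items():
            length = self.chrom_lengths[chrom]
            for a, b in regions:
                if not 1 <= a <= b <= length:
                    raise ValueError(f"planted region ({a}, {b}) outside {chrom}")


@dataclass
class SimTruth:
    planted_block_regions: dict[str, dict[str, list[tuple[int, int]]]]
    ne_true: dict[str, int]
    founders: dict[str, np.ndarray]   # population -> (n_founders, n_sites)


def _founder_haplotypes(rng: np.random.Generator, n_founders: int,
                        n_sites: int) -> np.ndarray:
    """Founders under a perfect phylogeny on a random genealogy.

    Every site's derived allele is carried by one clade of a random
    binary tree over the founders, so no two sites can exhibit all four
    gametes within the founder set.
    """
    if n_founders < 1:
        raise ValueError("need at least one founder")
    clades: list[list[int]] = [[i] for i in range(n_founders)]
    groups = [[i] for i in range(n_founders)]
    while len(groups) > 2:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = groups[i] + groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
        clades.append(merged)
    # the root (all founders) is excluded: it would be monomorphic
    hap = np.zeros((n_founders, n_sites), dtype=np.int8)
    which = rng.integers(0, len(clades), size=n_sites)
    for s in range(n_sites):
        hap[clades[which[s]], s] = 1
    return hap


def _gap_recomb_prob(pos: np.ndarray, recomb_rate: float,
                     planted: list[tuple[int, int]]) -> np.ndarray:
    gaps = np.diff(pos).astype(float)
    p = 1.0 - np.exp(-recomb_rate * gaps)
    for a, b in planted:
        blocked = (pos[:-1] < b) & (pos[1:] > a)
        p[blocked] = 0.0
    return p


def _evolve(rng: np.random.Generator, founders: np.ndarray, pos: np.ndarray,
            ne: int, n_generations: int, recomb_rate: float,
            planted: list[tuple[int, int]]) -> np.ndarray:
    """Wright-Fisher rounds of recombinant copying; returns 2*ne haplotypes."""
    n_slots = 2 * ne
    reps = int(np.ceil(n_slots / founders.shape[0]))
    pop = np.tile(founders, (reps, 1))[:n_slots].copy()
    p_gap = _gap_recomb_prob(pos, recomb_rate, planted)
    n_sites = len(pos)
    for _ in range(n_generations):
        pa = rng.integers(0, n_slots, size=n_slots)
        pb = rng.integers(0, n_slots, size=n_slots)
        if p_gap.size and p_gap.max() > 0:
            switches = rng.random((n_slots, n_sites - 1)) < p_gap
            anc = np.zeros((n_slots, n_sites), dtype=np.int8)
            anc[:, 1:] = np.cumsum(switches, axis=1) % 2
            pop = np.where(anc == 0, pop[pa], pop[pb]).astype(np.int8)
        else:
            pop = pop[pa].copy()
    return pop


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a multi-population phased panel and its ground truth.

    Deterministic under ``config.seed``.  Raises if a chromosome ends up
    with fewer than two polymorphic sites after the MAF filter.
    """
    ss = np.random.SeedSequence(config.seed)
    site_rng = np.random.default_rng(ss.spawn(1)[0])
    chrom_sites: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        n = max(2, int(round(config.site_density * length / 1000.0)))
        pos = np.sort(site_rng.choice(length, size=min(n, length),
                                      replace=False)) + 1
        chrom_sites[chrom] = pos

    pop_rngs = {p.label: np.random.default_rng(s)
                for p, s in zip(config.populations,
                                ss.spawn(1 + len(config.populations))[1:])}
    all_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    population: dict[str, str] = {}
    founders_out: dict[str, np.ndarray] = {}
    for pc in config.populations:
        rng = pop_rngs[pc.label]
        per_chrom = []
        founder_chrom = []
        for chrom, pos in chrom_sites.items():
            founders = _founder_haplotypes(rng, pc.n_founders, len(pos))
            founder_chrom.append(founders)
            planted = config.planted_block_regions.get(chrom, [])
            pool = _evolve(rng, founders, pos, pc.ne_true,
                           config.n_generations, config.recomb_rate, planted)
            take = rng.choice(pool.shape[0], size=2 * pc.n_individuals,
                              replace=pool.shape[0] < 2 * pc.n_individuals)
            per_chrom.append(pool[take])
        hap = np.concatenate(per_chrom, axis=1)
        if config.mutation_rate > 0:
            flips = rng.random(hap.shape) < config.mutation_rate
            hap = np.where(flips, 1 - hap, hap).astype(np.int8)
        all_rows.append(hap)
        founders_out[pc.label] = np.concatenate(founder_chrom, axis=1)
        for i in range(pc.n_individuals):
            sid = f"{pc.label}_{i:03d}"
            sample_ids.append(sid)
            population[sid] = pc.label

    hap = np.concatenate(all_rows, axis=0)
    sites = pd.DataFrame({
        "chrom": np.concatenate([[c] * len(p) for c, p in chrom_sites.items()]),
        "pos": np.concatenate(list(chrom_sites.values())),
    })
    sites["ref"] = "A"
    sites["alt"] = "G"
    maf = compute_maf(hap)
    keep = maf >= config.min_maf
    sites = sites.loc[keep].reset_index(drop=True)
    hap = hap[:, keep]
    founders_out = {p: f[:, keep] for p, f in founders_out.items()}
    sites["maf"] = compute_maf(hap)
    for chrom in config.chrom_lengths:
        on_chrom = (sites["chrom"] == chrom).sum()
        if on_chrom < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 polymorphic "
                             "sites after filtering; increase site_density or "
                             "founder diversity")
    panel = GenotypePanel(sites, hap, sample_ids, population)
    truth = SimTruth(
        planted_block_regions={pc.label: {c: list(r) for c, r in
                                          config.planted_block_regions.items()}
                               for pc in config.populations},
        ne_true={pc.label: pc.ne_true for pc in config.populations},
        founders=founders_out,
    )
    return panel, truth


def simulate_qtl_table(seed: int, n_qtls: int, span_range: tuple[int, int],
                       chrom_lengths: dict[str, int],
                       frac_large: float = 0.0) -> list[QtlRecord]:
    """Random QTL intervals; exactly round(frac_large * n_qtls) spans > 10 Mb."""
    lo, hi = span_range
    if lo <= 0 or hi < lo:
        raise ValueError("span_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    n_large = int(round(frac_large * n_qtls))
    chroms = list(chrom_lengths)
    records = []
    for i in range(n_qtls):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = chrom_lengths[chrom]
        if i < n_large:
            span = int(rng.integers(10_000_001, max(10_000_002, 2 * 10_000_001)))
        else:
            span = int(rng.integers(lo, min(hi, 10_000_000) + 1))
        start = int(rng.integers(1, max(2, length - span + 2)))
        records.append(QtlRecord(chrom, start, start + span - 1,
                                 f"T{i % 7}", f"QTL{i:04d}"))
    return records


def simulate_genes(seed: int, n_genes: int,
                   chrom_lengths: dict[str, int]) -> list[GeneRecord]:
    """Deterministic, non-overlapping gene intervals across chromosomes."""
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    genes: list[GeneRecord] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        share = round(n_genes * chrom_lengths[chrom] / total)
        if ci == len(chroms) - 1:
            share = n_genes - gid
        if share <= 0:
            continue
        slot = chrom_lengths[chrom] // share
        for s in range(share):
            lo = s * slot + 1
            width = max(2, min(slot // 2, int(rng.integers(2_000, 50_001))))
            start = int(rng.integers(lo, lo + max(1, slot - width)))
            genes.append(GeneRecord(chrom, start, start + width - 1,
                                    f"G{gid:04d}", f"gene{gid}"))
            gid += 1
    return genes
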