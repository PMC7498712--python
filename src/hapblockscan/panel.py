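"""Core containers for phased SNP panels.

A :class:`GenotypePanel` holds phased biallelic haplotypes (0 = REF,
1 = ALT) for a set of diploid individuals, together with per-site
metadata (chromosome, 1-based position, alleles, minor allele
frequency) and a population label per individual.  Haplotype rows come
in consecutive pairs: rows ``2*i`` and ``2*i + 1`` belong to individual
``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "maf"]


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNP site."""

    chrom: str
    pos: int  # 1-based physical position (bp)
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must be in [0, 0.5], got {self.maf}")


def compute_maf(haplotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site from a (n_hap, n_sites) 0/1 matrix."""
    freq = haplotypes.mean(axis=0)
    return np.minimum(freq, 1.0 - freq)


@dataclass
class GenotypePanel:
    """Phased biallelic haplotypes with site and population metadata.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, ref, alt, maf``;
        positions strictly increasing within each chromosome.
    haplotypes : numpy.ndarray
        ``(2 * n_individuals, n_sites)`` matrix of 0/1 alleles.
    sample_ids : list of str
        Individual identifiers, one per diploid individual.
    population : dict
        Mapping individual id -> population label.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str]
    population: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"haplotype rows ({self.haplotypes.shape[0]}) must equal "
                f"2 x individuals ({len(self.sample_ids)})"
            )
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("site table and haplotype matrix disagree on site count")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be 0 or 1")
        self.sites = self.sites.reset_index(drop=True)
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on {chrom} are not strictly increasing")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        return VariantSite(str(row["chrom"]), int(row["pos"]), str(row["ref"]),
                           str(row["alt"]), float(row["maf"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Site indices on a chromosome, in position order."""
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    # -- derived quantities ---------------------------------------------
    def recompute_maf(self) -> np.ndarray:
        return compute_maf(self.haplotypes)

    def genotypes(self) -> np.ndarray:
        """(n_individuals, n_sites) ALT-dosage matrix in {0, 1, 2}."""
        return self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]

    # -- subsetting ------------------------------------------------------
    def take_sites(self, indices: np.ndarray) -> "GenotypePanel":
        indices = np.asarray(indices)
        sub_sites = self.sites.iloc[indices].reset_index(drop=True)
        return GenotypePanel(sub_sites, self.haplotypes[:, indices],
                             list(self.sample_ids), dict(self.population))

    def take_individuals(self, ids: list[str]) -> "GenotypePanel":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        rows = []
        for s in ids:
            k = index[s]
            rows.extend((2 * k, 2 * k + 1))
        return GenotypePanel(self.sites.copy(), self.haplotypes[rows],
                             list(ids), {s: self.population[s] for s in ids
                                         if s in self.population})

    def with_fresh_maf(self) -> "GenotypePanel":
        """Return a copy whose stored MAF column is recomputed from alleles."""
        sites = self.sites.copy()
        sites["maf"] = compute_maf(self.haplotypes)
        return GenotypePanel(sites, self.haplotypes.copy(), list(self.sample_ids),
                             dict(self.population))
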