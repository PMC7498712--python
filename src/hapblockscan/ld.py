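"""Two-locus linkage disequilibrium statistics.

Works from phased haplotype counts: for loci with alleles coded 0/1,
``A``/``B`` denote allele 1 at the first and second locus.  Provides
D, D' and r-squared, an EM routine for unphased genotype input, the
likelihood-grid D' confidence interval used by Gabriel-style block
calling, and the resulting pair classification
(strong LD / strong recombination / uninformative).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel


class PairClass(enum.Enum):
    STRONG_LD = "strong_ld"
    STRONG_RECOMB = "strong_recomb"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class TwoLocusCounts:
    """Phased haplotype counts for a pair of biallelic loci."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    def __post_init__(self) -> None:
        if min(self.n_AB, self.n_Ab, self.n_aB, self.n_ab) < 0:
            raise ValueError("haplotype counts must be non-negative")

    @property
    def n_h(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    def freqs(self) -> np.ndarray:
        return np.array([self.n_AB, self.n_Ab, self.n_aB, self.n_ab], float) / self.n_h


@dataclass(frozen=True)
class PairLD:
    p_A: float
    p_B: float
    D: float
    d_prime: float
    r2: float
    ci_low: float | None = None
    ci_high: float | None = None
    distance_bp: int | None = None


def pair_counts(panel: GenotypePanel, i: int, j: int) -> TwoLocusCounts:
    """Tally the four two-locus haplotypes over phased rows."""
    if i == j:
        raise ValueError("need two distinct sites")
    if panel.sites.iloc[i]["chrom"] != panel.sites.iloc[j]["chrom"]:
        raise ValueError("sites are on different chromosomes")
    a = panel.haplotypes[:, i]
    b = panel.haplotypes[:, j]
    for name, col in (("i", a), ("j", b)):
        if col.min() == col.max():
            raise ValueError(f"MONOMORPHIC: site {name} has a single allele")
    n_AB = int(np.sum((a == 1) & (b == 1)))
    n_Ab = int(np.sum((a == 1) & (b == 0)))
    n_aB = int(np.sum((a == 0) & (b == 1)))
    n_ab = int(np.sum((a == 0) & (b == 0)))
    return TwoLocusCounts(n_AB, n_Ab, n_aB, n_ab)


def _d_max(p_a: float, p_b: float, d: float) -> float:
    if d > 0:
        return min(p_a * (1 - p_b), (1 - p_a) * p_b)
    return min(p_a * p_b, (1 - p_a) * (1 - p_b))


def pair_ld(counts: TwoLocusCounts) -> PairLD:
    """D, D' and r-squared from phased haplotype counts.

    Requires both loci polymorphic.  D' is |D| / D_max with D_max the
    frequency-constrained extreme of D in the direction of observed D;
    D' = 0 when D = 0.
    """
    n = counts.n_h
    if n == 0:
        raise ValueError("empty counts")
    p_ab_f = counts.n_AB / n
    p_a = (counts.n_AB + counts.n_Ab) / n
    p_b = (counts.n_AB + counts.n_aB) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("MONOMORPHIC: locus has a single allele")
    d = p_ab_f - p_a * p_b
    if d == 0:
        d_prime = 0.0
    else:
        d_prime = abs(d) / _d_max(p_a, p_b, d)
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return PairLD(p_a, p_b, d, min(d_prime, 1.0), min(r2, 1.0))


def em_hap_freqs(table: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 1000) -> tuple[np.ndarray, bool]:
    """EM haplotype frequencies (AB, Ab, aB, ab) from a 3x3 genotype table.

    ``table[g1, g2]`` counts individuals with ALT dosage ``g1`` at the
    first locus and ``g2`` at the second.  Only the double heterozygote
    is phase-ambiguous.  Returns (frequencies, converged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3) or t.sum() <= 0:
        raise ValueError("need a 3x3 genotype count table with positive total")
    n_hap = 2.0 * t.sum()
    # determinate haplotype contributions per cell
    known = np.array([
        2 * t[2, 2] + t[2, 1] + t[1, 2],          # AB
        2 * t[2, 0] + t[2, 1] + t[1, 0],          # Ab
        2 * t[0, 2] + t[1, 2] + t[0, 1],          # aB
        2 * t[0, 0] + t[1, 0] + t[0, 1],          # ab
    ])
    m = t[1, 1]
    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        cis, trans = freqs[0] * freqs[3], freqs[1] * freqs[2]
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        expected = known + m * np.array([w, 1 - w, 1 - w, w])
        new = expected / n_hap
        if np.max(np.abs(new - freqs)) < tol:
            return new, True
        freqs = new
    return freqs, False


def dprime_ci(counts: TwoLocusCounts, grid_points: int = 101) -> tuple[float, float]:
    """Likelihood-grid confidence interval for D'.

    The multinomial likelihood of the observed haplotype counts is
    evaluated at D' values on a uniform grid over [0, 1], holding allele
    frequencies at their observed values and signing D toward the
    observed D.  After normalising the grid likelihood to sum to 1,
    ci_low is the smallest grid value at which the cumulative sum from 0
    exceeds 0.05 and ci_high the smallest at which it exceeds 0.95.
    """
    n = counts.n_h
    obs = np.array([counts.n_AB, counts.n_Ab, counts.n_aB, counts.n_ab], float)
    p_a = (counts.n_AB + counts.n_Ab) / n
    p_b = (counts.n_AB + counts.n_aB) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("MONOMORPHIC: locus has a single allele")
    d_obs = counts.n_AB / n - p_a * p_b
    sign = -1.0 if d_obs < 0 else 1.0
    d_max = _d_max(p_a, p_b, sign)
    grid = np.linspace(0.0, 1.0, grid_points)
    base = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                     (1 - p_a) * (1 - p_b)])
    delta = sign * d_max * np.array([1.0, -1.0, -1.0, 1.0])
    f = np.clip(base[None, :] + grid[:, None] * delta[None, :], 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs[None, :] > 0, obs[None, :] * np.log(f), 0.0)
    loglik = terms.sum(axis=1)
    loglik[np.any((f <= 0) & (obs[None, :] > 0), axis=1)] = -np.inf
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cum = np.cumsum(w)
    low_idx = int(np.argmax(cum > 0.05))
    high_idx = int(np.argmax(cum > 0.95))
    return float(grid[low_idx]), float(grid[high_idx])


def classify_pair(ci: tuple[float, float], strong_low: float = 0.70,
                  strong_high: float = 0.98,
                  recomb_high: float = 0.90) -> PairClass:
    """Gabriel pair classification from a D' confidence interval."""
    low, high = ci
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError(f"invalid CI ({low}, {high})")
    if low >= strong_low and high >= strong_high:
        return PairClass.STRONG_LD
    if high < recomb_high:
        return PairClass.STRONG_RECOMB
    return PairClass.UNINFORMATIVE


def pair_ld_full(panel: GenotypePanel, i: int, j: int,
                 with_ci: bool = False) -> PairLD:
    """Convenience: counts -> PairLD with distance and optional D' CI."""
    c = pair_counts(panel, i, j)
    ld = pair_ld(c)
    lo = hi = None
    if with_ci:
        lo, hi = dprime_ci(c)
    dist = abs(int(panel.sites.iloc[i]["pos"]) - int(panel.sites.iloc[j]["pos"]))
    return PairLD(ld.p_A, ld.p_B, ld.D, ld.d_prime, ld.r2, lo, hi, dist)
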