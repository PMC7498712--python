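"""Genomic interval records: haplotype blocks, QTLs and genes.

All coordinates are 1-based and inclusive; the length of an interval is
``end - start + 1`` bp.  (A block of two adjacent SNPs therefore has
length 2 bp = 0.002 kb.)  BED files are converted to and from this
convention at the IO boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class QtlRecord:
    chrom: str
    start: int
    end: int
    trait_abbrev: str
    qtl_id: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"QTL {self.qtl_id}: end < start")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    gene_id: str
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class HaploBlock:
    """A run of SNPs forming a haplotype block.

    ``start``/``end`` are the positions of the first and last member SNP;
    ``snp_indices`` index into the panel the block was called on.
    """

    chrom: str
    start: int
    end: int
    snp_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.snp_indices:
            if len(self.snp_indices) < 2:
                raise ValueError("a block needs at least 2 SNPs")
            if any(b <= a for a, b in zip(self.snp_indices, self.snp_indices[1:])):
                raise ValueError("snp_indices must be strictly increasing")
        if self.end - self.start + 1 < 2:
            raise ValueError("block length must be >= 2 bp")

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
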