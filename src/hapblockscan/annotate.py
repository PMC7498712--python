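"""QTL overlap, gene mapping and EASE-score term enrichment.

QTL intervals longer than 10 Mb are discarded before overlap testing;
a block/QTL pair is reported when their overlap exceeds half the length
of the shorter feature (so containment of the shorter feature always
qualifies).  Gene-set enrichment uses the EASE score — a conservative
one-sided Fisher exact test with one hit removed from the overlap
cell — with Benjamini-Hochberg FDR across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from intervaltree import IntervalTree
from scipy.stats import false_discovery_control, hypergeom

from .regions import GeneRecord, HaploBlock, QtlRecord, overlap_bp


@dataclass(frozen=True)
class OverlapHit:
    block: HaploBlock
    feature: Union[QtlRecord, GeneRecord]
    overlap_bp: int
    overlap_fraction: float  # overlap over the shorter feature's length


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int        # term genes in the gene list
    n: int        # gene-list size
    K: int        # term genes in the background
    N: int        # background size
    ease_p: float
    bh_fdr: float
    genes: tuple[str, ...]


def filter_qtls(qtls: list[QtlRecord],
                max_span_bp: int = 10_000_000) -> tuple[list[QtlRecord], int]:
    """Retain QTLs with span <= ``max_span_bp`` (inclusive).

    Returns (retained records, number removed).
    """
    kept = [q for q in qtls if q.span_bp <= max_span_bp]
    return kept, len(qtls) - len(kept)


def block_qtl_overlap(blocks: list[HaploBlock], qtls: list[QtlRecord],
                      min_fraction: float = 0.5) -> list[OverlapHit]:
    """Block/QTL pairs whose overlap exceeds ``min_fraction`` of the
    shorter feature (strictly)."""
    by_chrom: dict[str, IntervalTree] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end + 1, q)
    hits = []
    for b in blocks:
        tree = by_chrom.get(b.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(b.start, b.end + 1)):
            q: QtlRecord = iv.data
            ov = overlap_bp(b.start, b.end, q.start, q.end)
            shorter = min(b.length_bp, q.span_bp)
            if ov > min_fraction * shorter:
                hits.append(OverlapHit(b, q, ov, ov / shorter))
    return hits


def map_genes(blocks: list[HaploBlock],
              genes: list[GeneRecord]) -> dict[int, list[GeneRecord]]:
    """Genes overlapping each block by >= 1 bp, keyed by block index."""
    by_chrom: dict[str, IntervalTree] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    mapping: dict[int, list[GeneRecord]] = {}
    for bi, b in enumerate(blocks):
        tree = by_chrom.get(b.chrom)
        found = ([] if tree is None else
                 sorted((iv.data for iv in tree.overlap(b.start, b.end + 1)),
                        key=lambda g: (g.start, g.gene_id)))
        mapping[bi] = found
    return mapping


def ease_p_value(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact p with the list-hit cell reduced by one.

    Equivalent to the Fisher 'greater' p of the 2x2 table
    (k-1, n-k+1; K-k+1, N-K-n+k-1), i.e. the hypergeometric tail
    P(X >= k-1) for X ~ HG(N, K, n); with a single hit (k = 1) the
    statistic is 1 by construction.
    """
    if not 1 <= k <= min(n, K) or n > N or K > N:
        raise ValueError("inconsistent enrichment table")
    return float(hypergeom.sf(k - 2, N, K, n))


def ease_enrichment(gene_list: list[str], term_sets: dict[str, set[str]],
                    background: list[str]) -> list[EnrichmentResult]:
    """EASE enrichment of ``gene_list`` against term sets over a background.

    Terms without any list hit are skipped; Benjamini-Hochberg FDR is
    computed across the tested terms; results are sorted by ascending
    EASE p-value.
    """
    bg = set(background)
    gl = set(gene_list)
    if not gl <= bg:
        raise ValueError("gene list must be a subset of the background")
    n, N = len(gl), len(bg)
    tested = []
    for term, genes in term_sets.items():
        genes = set(genes)
        if not genes <= bg:
            raise ValueError(f"term {term} has genes outside the background")
        hits = gl & genes
        if not hits:
            continue
        p = ease_p_value(len(hits), n, len(genes), N)
        tested.append((term, len(hits), len(genes), p, tuple(sorted(hits))))
    if not tested:
        return []
    fdr = false_discovery_control([t[3] for t in tested], method="bh")
    results = [EnrichmentResult(term=term, k=k, n=n, K=K, N=N, ease_p=p,
                                bh_fdr=float(q), genes=genes)
               for (term, k, K, p, genes), q in zip(tested, fdr)]
    results.sort(key=lambda r: (r.ease_p, r.term))
    return results


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT term file: term, description, then gene ids, tab-separated."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def write_qtl_hits(hits: list[OverlapHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: chrom\tblock_start\tblock_end\tlength_kb\tn_snps"
                 "\ttrait_abbrev\tqtl_id\toverlap_bp\toverlap_fraction\n")
        for h in hits:
            b = h.block
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.length_kb:.3f}"
                     f"\t{b.n_snps}\t{h.feature.trait_abbrev}\t{h.feature.qtl_id}"
                     f"\t{h.overlap_bp}\t{h.overlap_fraction:.4f}\n")


def write_enrichment(results: list[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: term\tk\tn\tK\tN\tease_p\tbh_fdr\tgenes\n")
        for r in results:
            fh.write(f"{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.ease_p:.6g}"
                     f"\t{r.bh_fdr:.6g}\t{','.join(r.genes)}\n")
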