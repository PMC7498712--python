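"""Haplotype-block detection and block summary statistics.

Two block definitions are provided:

* Gabriel-style blocks: site pairs are classified from the D'
  confidence interval as strong LD, strong recombination or
  uninformative; a candidate block requires strong LD for its outermost
  pair and at least ``inform_frac`` strong-LD pairs among its
  informative internal pairs; candidates are accepted greedily by
  descending span without sharing markers.
* Four-gamete blocks: a block extends while every pair of member sites
  shows at most three of the four two-locus gametes at or above a
  frequency threshold; a fourth gamete at that frequency marks a
  historical recombination event and closes the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld import PairClass, TwoLocusCounts, classify_pair, dprime_ci
from .panel import GenotypePanel
from .regions import HaploBlock

_STRONG, _RECOMB, _UNINF = 0, 1, 2


def _pair_class_code(hap: np.ndarray, a: int, b: int, strong_low: float,
                     strong_high: float, recomb_high: float) -> int:
    ha, hb = hap[:, a], hap[:, b]
    counts = TwoLocusCounts(int(((ha == 1) & (hb == 1)).sum()),
                            int(((ha == 1) & (hb == 0)).sum()),
                            int(((ha == 0) & (hb == 1)).sum()),
                            int(((ha == 0) & (hb == 0)).sum()))
    cls = classify_pair(dprime_ci(counts), strong_low, strong_high, recomb_high)
    return {PairClass.STRONG_LD: _STRONG, PairClass.STRONG_RECOMB: _RECOMB,
            PairClass.UNINFORMATIVE: _UNINF}[cls]


def gabriel_blocks(panel: GenotypePanel, chrom: str, strong_low: float = 0.70,
                   strong_high: float = 0.98, recomb_high: float = 0.90,
                   inform_frac: float = 0.95, max_span_kb: float = 200.0,
                   min_maf: float = 0.05) -> list[HaploBlock]:
    """Gabriel-criteria haplotype blocks on one chromosome.

    Sites with MAF below ``min_maf`` are excluded from pairing.  The
    same uniform pair criteria apply to all pair spans.  Accepted blocks
    never share markers and never exceed ``max_span_kb``.
    """
    idx = panel.chrom_indices(chrom)
    maf = panel.sites["maf"].to_numpy()[idx]
    idx = idx[maf >= max(min_maf, np.finfo(float).tiny)]
    m = len(idx)
    if m < 2:
        return []
    pos = panel.sites["pos"].to_numpy()[idx]
    hap = panel.haplotypes
    span_bp = int(round(max_span_kb * 1000))

    # classify every pair within the span window
    cls: list[np.ndarray] = []
    for a in range(m):
        b_hi = int(np.searchsorted(pos, pos[a] + span_bp - 1, side="right"))
        codes = np.array([_pair_class_code(hap, idx[a], idx[b], strong_low,
                                           strong_high, recomb_high)
                          for b in range(a + 1, b_hi)], dtype=np.int8)
        cls.append(codes)

    # enumerate candidate blocks
    candidates = []  # (span_bp, start_local, end_local)
    for i in range(m):
        n_strong = n_recomb = 0
        for j in range(i + 1, i + 1 + len(cls[i])):
            new = np.array([cls[a][j - a - 1] for a in range(i, j)])
            n_strong += int((new == _STRONG).sum())
            n_recomb += int((new == _RECOMB).sum())
            if cls[i][j - i - 1] != _STRONG:
                continue
            informative = n_strong + n_recomb
            if informative > 0 and n_strong / informative >= inform_frac:
                candidates.append((int(pos[j] - pos[i] + 1), i, j))

    # greedy acceptance: descending span, ties by leftmost start
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for _, i, j in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        blocks.append(HaploBlock(chrom, int(pos[i]), int(pos[j]),
                                 [int(k) for k in idx[i:j + 1]]))
    blocks.sort(key=lambda b: b.start)
    return blocks


def four_gamete_blocks(panel: GenotypePanel, chrom: str,
                       min_hap_freq: float = 0.01) -> list[HaploBlock]:
    """Greedy left-to-right four-gamete-rule partition of a chromosome.

    A gamete counts as present when its frequency is >= ``min_hap_freq``;
    observing all four between any pair of member sites closes the block
    at the previous site.  Monomorphic sites are skipped.  Only blocks of
    at least two SNPs are returned.
    """
    idx = panel.chrom_indices(chrom)
    maf = panel.sites["maf"].to_numpy()[idx]
    idx = idx[maf > 0]
    if len(idx) < 2:
        return []
    hap = panel.haplotypes
    n_h = hap.shape[0]
    pos = panel.sites["pos"].to_numpy()
    min_count = min_hap_freq * n_h

    def four_gametes(a: int, b: int) -> bool:
        ha, hb = hap[:, a], hap[:, b]
        c = np.array([((ha == 1) & (hb == 1)).sum(), ((ha == 1) & (hb == 0)).sum(),
                      ((ha == 0) & (hb == 1)).sum(), ((ha == 0) & (hb == 0)).sum()])
        return bool(np.all(c >= min_count))

    blocks = []
    current = [int(idx[0])]
    for g in idx[1:]:
        g = int(g)
        if any(four_gametes(a, g) for a in current):
            if len(current) >= 2:
                blocks.append(HaploBlock(chrom, int(pos[current[0]]),
                                         int(pos[current[-1]]), current))
            current = [g]
        else:
            current.append(g)
    if len(current) >= 2:
        blocks.append(HaploBlock(chrom, int(pos[current[0]]),
                                 int(pos[current[-1]]), current))
    return blocks


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def aggregate_summary(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Derive the per-chromosome means/percentages and the grand-total row.

    Input columns: ``chrom, n_blocks, total_length_kb, min_kb, max_kb,
    n_snps_in_blocks, min_snps, max_snps``.  Adds ``mean_kb`` (total
    length / block count), ``mean_snps``, and ``pct_snps_in_blocks``
    (chromosome SNPs-in-blocks over all SNPs-in-blocks, x100).  The
    grand-total row sums the counts; its mean block size is the
    unweighted mean of the per-chromosome mean block sizes.
    """
    df = per_chrom.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["mean_kb"] = np.where(df["n_blocks"] > 0,
                                 df["total_length_kb"] / df["n_blocks"], 0.0)
        df["mean_snps"] = np.where(df["n_blocks"] > 0,
                                   df["n_snps_in_blocks"] / df["n_blocks"], 0.0)
    total_snps = df["n_snps_in_blocks"].sum()
    df["pct_snps_in_blocks"] = np.where(
        total_snps > 0, df["n_snps_in_blocks"] / max(total_snps, 1) * 100.0, 0.0)
    nonzero = df["n_blocks"] > 0
    total = {
        "chrom": "Total",
        "n_blocks": df["n_blocks"].sum(),
        "total_length_kb": df["total_length_kb"].sum(),
        "min_kb": df.loc[nonzero, "min_kb"].min() if nonzero.any() else np.nan,
        "max_kb": df.loc[nonzero, "max_kb"].max() if nonzero.any() else np.nan,
        "n_snps_in_blocks": total_snps,
        "min_snps": df.loc[nonzero, "min_snps"].min() if nonzero.any() else np.nan,
        "max_snps": df.loc[nonzero, "max_snps"].max() if nonzero.any() else np.nan,
        "mean_kb": df.loc[nonzero, "mean_kb"].mean() if nonzero.any() else 0.0,
        "mean_snps": df.loc[nonzero, "mean_snps"].mean() if nonzero.any() else 0.0,
        "pct_snps_in_blocks": 100.0 if total_snps > 0 else 0.0,
    }
    out = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    cols = ["chrom", "n_blocks", "total_length_kb", "mean_kb", "min_kb",
            "max_kb", "n_snps_in_blocks", "mean_snps", "min_snps", "max_snps",
            "pct_snps_in_blocks"]
    return out[cols]


def clustering_rate(n_snps_in_blocks: int, n_snps_total: int) -> float:
    """Percentage of a panel's SNPs clustered into haplotype blocks."""
    if n_snps_total <= 0:
        raise ValueError("total SNP count must be positive")
    return n_snps_in_blocks / n_snps_total * 100.0


def block_summary(blocks: list[HaploBlock], panel: GenotypePanel) -> pd.DataFrame:
    """Per-chromosome block statistics plus a grand-total row.

    Chromosomes present in the panel but without blocks appear as rows
    of zeros.
    """
    by_chrom: dict[str, list[HaploBlock]] = {c: [] for c in panel.chromosomes()}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    rows = []
    for chrom, bl in by_chrom.items():
        kb = np.array([b.length_kb for b in bl])
        snps = np.array([b.n_snps for b in bl])
        rows.append({
            "chrom": chrom,
            "n_blocks": len(bl),
            "total_length_kb": kb.sum() if len(bl) else 0.0,
            "min_kb": kb.min() if len(bl) else 0.0,
            "max_kb": kb.max() if len(bl) else 0.0,
            "n_snps_in_blocks": int(snps.sum()) if len(bl) else 0,
            "min_snps": int(snps.min()) if len(bl) else 0,
            "max_snps": int(snps.max()) if len(bl) else 0,
        })
    return aggregate_summary(pd.DataFrame(rows))


@dataclass(frozen=True)
class SelectedBlock:
    block: HaploBlock
    by_length: bool
    by_snps: bool


def select_top_blocks(blocks: list[HaploBlock], k_length: int = 10,
                      k_snps: int = 10) -> list[SelectedBlock]:
    """Union of the top-k blocks by length and by SNP count.

    A block ranking in both lists appears once with both flags set.
    Rank ties break by (chrom, start) ascending; the result is ordered
    by (chrom, start).
    """
    if not blocks:
        raise ValueError("no blocks to select from")
    by_len = sorted(blocks, key=lambda b: (-b.length_bp, b.chrom, b.start))[:k_length]
    by_snp = sorted(blocks, key=lambda b: (-b.n_snps, b.chrom, b.start))[:k_snps]
    len_ids = {id(b) for b in by_len}
    snp_ids = {id(b) for b in by_snp}
    chosen = {id(b): b for b in [*by_len, *by_snp]}
    out = [SelectedBlock(b, id(b) in len_ids, id(b) in snp_ids)
           for b in chosen.values()]
    out.sort(key=lambda s: (s.block.chrom, s.block.start))
    return out


def write_block_summary(summary: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(summary.columns) + "\n")
        summary.to_csv(fh, sep="\t", header=False, index=False,
                       float_format="%.4f")
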