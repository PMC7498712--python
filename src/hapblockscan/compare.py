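"""Shared and unique haplotype-block regions across populations.

Sharing between two populations is counted block-wise: the (r, c) entry
of the sharing matrix is the percentage of population r's blocks that
overlap (by at least 1 bp) any block of population c — generally
asymmetric.  A length-weighted variant and multi-way intersections of
block coverage are also provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regions import HaploBlock


def _trees(blocks: list[HaploBlock]) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = {}
    for b in blocks:
        # half-open tree coordinates: [start, end + 1)
        by_chrom.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end + 1)
    return by_chrom


def _overlaps_any(block: HaploBlock, trees: dict[str, IntervalTree]) -> bool:
    t = trees.get(block.chrom)
    return bool(t and t.overlaps(block.start, block.end + 1))


def sharing_matrix(block_sets: dict[str, list[HaploBlock]],
                   length_weighted: bool = False) -> pd.DataFrame:
    """Percentage of each focal population's blocks shared with each partner.

    With ``length_weighted`` the entry is instead the percentage of the
    focal population's total block length covered by the partner's
    blocks.  Rows with no blocks are reported as missing (NaN).
    """
    pops = list(block_sets)
    if len(pops) < 2:
        raise ValueError("need >= 2 block sets")
    trees = {p: _trees(block_sets[p]) for p in pops}
    mat = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for r in pops:
        focal = block_sets[r]
        if not focal:
            continue
        for c in pops:
            if c == r:
                mat.loc[r, r] = 100.0
                continue
            if length_weighted:
                total = sum(b.length_bp for b in focal)
                covered = sum(_covered_bp(b, trees[c]) for b in focal)
                mat.loc[r, c] = covered / total * 100.0
            else:
                n_shared = sum(_overlaps_any(b, trees[c]) for b in focal)
                mat.loc[r, c] = n_shared / len(focal) * 100.0
    return mat


def _covered_bp(block: HaploBlock, trees: dict[str, IntervalTree]) -> int:
    t = trees.get(block.chrom)
    if not t:
        return 0
    pieces = sorted((max(iv.begin, block.start), min(iv.end, block.end + 1))
                    for iv in t.overlap(block.start, block.end + 1))
    covered, cursor = 0, block.start
    for lo, hi in pieces:
        lo = max(lo, cursor)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    return covered


def unique_blocks(block_sets: dict[str, list[HaploBlock]],
                  focal: str) -> list[HaploBlock]:
    """Focal-population blocks with zero overlap against every other set."""
    if focal not in block_sets:
        raise KeyError(focal)
    others = [_trees(bl) for p, bl in block_sets.items() if p != focal]
    return [b for b in block_sets[focal]
            if not any(_overlaps_any(b, t) for t in others)]


def multiway_shared_length(block_sets: dict[str, list[HaploBlock]],
                           members: list[str]) -> int:
    """Total bp covered by blocks of *every* member population.

    Computed chromosome-wise by an endpoint sweep over the union of the
    members' block intervals, counting bases where the coverage depth
    equals the number of members.
    """
    if len(members) < 2:
        raise ValueError("need >= 2 member populations")
    chroms = {b.chrom for m in members for b in block_sets[m]}
    total = 0
    k = len(members)
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for m in members:
            tree = _trees([b for b in block_sets[m] if b.chrom == chrom])
            merged = tree.get(chrom, IntervalTree())
            merged.merge_overlaps()
            for iv in merged:
                events.append((iv.begin, 1))
                events.append((iv.end, -1))
        events.sort()
        depth, prev = 0, None
        for x, delta in events:
            if depth == k and prev is not None:
                total += x - prev
            depth += delta
            prev = x
    return total


def shared_regions_bed(block_sets: dict[str, list[HaploBlock]],
                       members: list[str]) -> list[tuple[str, int, int]]:
    """1-based inclusive intervals covered by blocks of every member."""
    chroms = sorted({b.chrom for m in members for b in block_sets[m]})
    out = []
    k = len(members)
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for m in members:
            tree = _trees([b for b in block_sets[m] if b.chrom == chrom])
            merged = tree.get(chrom, IntervalTree())
            merged.merge_overlaps()
            for iv in merged:
                events.append((iv.begin, 1))
                events.append((iv.end, -1))
        events.sort()
        depth, start = 0, None
        for x, delta in events:
            depth += delta
            if depth == k and delta > 0:
                start = x
            elif start is not None and depth < k:
                out.append((chrom, start, x - 1))
                start = None
    return out
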