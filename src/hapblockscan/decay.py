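"""Genome-scale LD decay and LD-based effective population size.

The decay of r-squared with physical distance d is modelled with the
drift-recombination expectation E(r2) = 1 / (1 + 4*beta*d) (d in kb),
fitted by nonlinear least squares.  Mean r2 in distance bins is
converted to an effective-population-size trajectory through
E(r2) = 1 / (alpha + 4*Ne*c) with the generation mapping t = 1/(2c),
where c is the recombination fraction of the bin midpoint under a
physical-to-genetic map (default 100 Mb = 1 Morgan).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ld import pair_ld, TwoLocusCounts
from .panel import GenotypePanel

logger = logging.getLogger("hapblockscan")

BIN_EDGES_KB = [0, 10, 20, 40, 60, 100, 200, 500, 1000]
SVED_GRID_KB = [0, 4, 8, 12, 20, 30, 40, 60, 80, 100, 120, 160, 200, 250,
                300, 360, 460, 620, 800, 1000]


def sved_curve(d_kb: np.ndarray, beta: float) -> np.ndarray:
    """Expected r2 at distance d (kb) under the hyperbolic decay model."""
    return 1.0 / (1.0 + 4.0 * beta * np.asarray(d_kb, float))


@dataclass
class DecayFit:
    """Result of fitting r2 = 1/(1 + 4*beta*d) to LD observations."""

    beta: float                 # per-kb decay coefficient
    grid_kb: np.ndarray
    fitted: np.ndarray          # curve evaluated on grid_kb
    residuals: np.ndarray       # observed - fitted at the observation distances
    n_obs: int


@dataclass(frozen=True)
class NePoint:
    t: int            # generations ago, 1/(2c) rounded
    c_t: float        # recombination fraction (Morgans) at the bin midpoint
    ne: float
    r2_adj: float     # sample-size-corrected mean r2
    alpha: float


def pairwise_ld(panel: GenotypePanel, chrom: str,
                max_window_bp: int = 1_000_000) -> pd.DataFrame:
    """r2 for all site pairs on ``chrom`` within ``max_window_bp``.

    Monomorphic sites are skipped.  Returns a DataFrame with columns
    ``i, j, distance_bp, r2`` (panel site indices).
    """
    idx = panel.chrom_indices(chrom)
    hap = panel.haplotypes[:, idx].astype(float)
    pos = panel.sites["pos"].to_numpy()[idx]
    n_h = hap.shape[0]
    freq = hap.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    keep = np.flatnonzero(poly)
    hap, pos, idx = hap[:, keep], pos[keep], idx[keep]
    freq = freq[keep]
    centered = hap - freq
    var = (centered ** 2).mean(axis=0)
    out_i, out_j, out_d, out_r2 = [], [], [], []
    for a in range(len(idx)):
        hi = np.searchsorted(pos, pos[a] + max_window_bp, side="right")
        if hi <= a + 1:
            continue
        cov = centered[:, a] @ centered[:, a + 1:hi] / n_h
        r2 = cov ** 2 / (var[a] * var[a + 1:hi])
        out_i.append(np.full(hi - a - 1, idx[a]))
        out_j.append(idx[a + 1:hi])
        out_d.append(pos[a + 1:hi] - pos[a])
        out_r2.append(np.minimum(r2, 1.0))
    if not out_i:
        return pd.DataFrame(columns=["i", "j", "distance_bp", "r2"])
    return pd.DataFrame({
        "i": np.concatenate(out_i), "j": np.concatenate(out_j),
        "distance_bp": np.concatenate(out_d), "r2": np.concatenate(out_r2),
    })


def adjacent_ld(panel: GenotypePanel, chrom: str) -> np.ndarray:
    """r2 between physically consecutive polymorphic sites on a chromosome."""
    idx = panel.chrom_indices(chrom)
    maf = panel.sites["maf"].to_numpy()[idx]
    idx = idx[maf > 0]
    vals = []
    for a, b in zip(idx, idx[1:]):
        ha, hb = panel.haplotypes[:, a], panel.haplotypes[:, b]
        c = TwoLocusCounts(int(((ha == 1) & (hb == 1)).sum()),
                           int(((ha == 1) & (hb == 0)).sum()),
                           int(((ha == 0) & (hb == 1)).sum()),
                           int(((ha == 0) & (hb == 0)).sum()))
        vals.append(pair_ld(c).r2)
    return np.asarray(vals)


def bin_ld(observations: pd.DataFrame,
           bin_edges_kb: Sequence[float] = BIN_EDGES_KB) -> pd.DataFrame:
    """Mean r2 per distance bin; bins are left-open/right-closed in kb.

    Observations beyond the last edge are excluded; their count is
    stored in ``result.attrs['n_excluded']``.  Empty bins have
    ``n_pairs = 0`` and NaN mean.
    """
    edges = np.asarray(bin_edges_kb, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d_kb = observations["distance_bp"].to_numpy() / 1000.0
    r2 = observations["r2"].to_numpy()
    inside = (d_kb > edges[0]) & (d_kb <= edges[-1])
    which = np.searchsorted(edges, d_kb[inside], side="left") - 1
    n_bins = len(edges) - 1
    n_pairs = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    table = pd.DataFrame({
        "bin_lo_kb": edges[:-1], "bin_hi_kb": edges[1:],
        "mean_r2": means, "n_pairs": n_pairs,
    })
    table.attrs["n_excluded"] = int(len(d_kb) - inside.sum())
    return table


def fit_sved(observations: pd.DataFrame,
             distance_grid_kb: Sequence[float] = SVED_GRID_KB) -> DecayFit:
    """Least-squares fit of beta in r2 = 1/(1 + 4*beta*d).

    ``observations`` may be raw pairs (``distance_bp``/``r2``) or a
    binned table from :func:`bin_ld` (midpoints are used).
    """
    if "distance_bp" in observations.columns:
        d_kb = observations["distance_bp"].to_numpy() / 1000.0
        r2 = observations["r2"].to_numpy()
    else:
        good = observations["n_pairs"].to_numpy() > 0
        d_kb = ((observations["bin_lo_kb"] + observations["bin_hi_kb"]) / 2.0
                ).to_numpy()[good]
        r2 = observations["mean_r2"].to_numpy()[good]
    if len(np.unique(d_kb[d_kb > 0])) < 1 or len(np.unique(d_kb)) < 2:
        raise ValueError("UNIDENTIFIABLE: need observations at >= 2 distinct "
                         "distances, not all zero")
    beta0 = 0.01
    popt, _ = curve_fit(sved_curve, d_kb, r2, p0=[beta0],
                        bounds=(0.0, np.inf), xtol=1e-12, ftol=1e-12,
                        maxfev=10000)
    beta = float(popt[0])
    grid = np.asarray(distance_grid_kb, float)
    return DecayFit(beta, grid, sved_curve(grid, beta),
                    r2 - sved_curve(d_kb, beta), len(d_kb))


def identity_map(d_morgans: float) -> float:
    """100 Mb = 1 Morgan: recombination fraction equals map distance."""
    return d_morgans


def haldane_map(d_morgans: float) -> float:
    """Haldane mapping from map distance (Morgans) to recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def estimate_ne(binned: pd.DataFrame, n_individuals: int, alpha: float = 2.2,
                morgans_per_bp: float = 1e-8,
                mapping: Callable[[float], float] = identity_map) -> list[NePoint]:
    """Ne trajectory from distance-binned mean r2.

    Per bin: c = mapping(midpoint_bp * morgans_per_bp); t = 1/(2c)
    rounded to the nearest generation; r2_adj = mean r2 - 1/(2n)
    (sample-size correction); Ne = (1/r2_adj - alpha) / (4c).  Bins
    where the corrected r2 is incompatible with a positive Ne are
    dropped with a warning.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    points: list[NePoint] = []
    for row in binned.itertuples(index=False):
        if row.n_pairs < 1 or not np.isfinite(row.mean_r2):
            continue
        mid_bp = (row.bin_lo_kb + row.bin_hi_kb) / 2.0 * 1000.0
        c = float(mapping(mid_bp * morgans_per_bp))
        if c <= 0:
            continue
        r2_adj = row.mean_r2 - 1.0 / (2.0 * n_individuals)
        if r2_adj <= 0 or (1.0 / r2_adj - alpha) <= 0:
            logger.warning("bin (%g, %g] kb dropped: corrected r2 %.4f is not "
                           "compatible with a positive Ne", row.bin_lo_kb,
                           row.bin_hi_kb, r2_adj)
            continue
        ne = (1.0 / r2_adj - alpha) / (4.0 * c)
        points.append(NePoint(int(round(1.0 / (2.0 * c))), c, ne, r2_adj, alpha))
    return points


def write_decay_table(binned: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: bin_lo_kb\tbin_hi_kb\tmean_r2\tn_pairs\n")
        binned.to_csv(fh, sep="\t", header=False, index=False)


def write_ne_table(points: list[NePoint], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: t_generations\tc_morgans\tne\tr2_adj\talpha\n")
        for p in points:
            fh.write(f"{p.t}\t{p.c_t:.6g}\t{p.ne:.4f}\t{p.r2_adj:.6f}\t{p.alpha}\n")


def plot_decay(binned: pd.DataFrame, fit: DecayFit | None, path: str) -> None:
    """Simple diagnostic plot of binned r2 and the fitted decay curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = (binned["bin_lo_kb"] + binned["bin_hi_kb"]) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mid, binned["mean_r2"], "o-", label="binned mean $r^2$")
    if fit is not None:
        ax.plot(fit.grid_kb, fit.fitted, "--",
                label=rf"$1/(1+4\beta d)$, $\beta$={fit.beta:.3g}/kb")
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
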