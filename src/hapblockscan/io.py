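"""Readers, writers and site-level filtering.

VCF input must be phased (``|`` genotype separator) and biallelic;
missing genotypes are rejected because imputation is out of scope.
On-disk BED is 0-based half-open and is converted to the package's
1-based inclusive convention on read (and back on write).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import GenotypePanel, compute_maf
from .regions import GeneRecord, HaploBlock, QtlRecord

logger = logging.getLogger("hapblockscan")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, populations: dict[str, str] | None = None) -> GenotypePanel:
    """Read phased biallelic SNPs from a VCF file into a panel.

    REF is coded 0 and ALT 1.  Raises ``ValueError`` for multiallelic
    records, missing genotypes, or unphased genotypes, naming the
    offending record.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    haps = []
    for var in vcf:
        label = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic record at {label}")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for k, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {label}, sample {samples[k]}")
            if not phased:
                raise ValueError(f"unphased genotype at {label}, sample {samples[k]}")
            col[2 * k] = a
            col[2 * k + 1] = b
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        haps.append(col)
    hap = np.array(haps, dtype=np.int8).T if haps else np.zeros((2 * len(samples), 0), np.int8)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    sites["maf"] = compute_maf(hap)
    return GenotypePanel(sites, hap, samples, dict(populations or {}))


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as a minimal phased VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.chromosomes():
            pos = panel.sites.loc[panel.sites["chrom"] == chrom, "pos"]
            fh.write(f"##contig=<ID={chrom},length={int(pos.max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        hap = panel.haplotypes
        for j in range(panel.n_sites):
            row = panel.sites.iloc[j]
            gts = "\t".join(f"{hap[2 * k, j]}|{hap[2 * k + 1, j]}"
                            for k in range(panel.n_individuals))
            fh.write(f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filtering and splitting
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    panel: GenotypePanel
    n_removed_maf: int
    n_removed_chrom: int


def filter_sites(panel: GenotypePanel, min_maf: float = 0.05,
                 drop_chroms: set[str] | None = None) -> FilterResult:
    """Retain sites with MAF >= ``min_maf`` (inclusive) outside ``drop_chroms``."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    drop_chroms = set(drop_chroms or ())
    chrom_bad = panel.sites["chrom"].isin(drop_chroms).to_numpy()
    maf_bad = (panel.sites["maf"].to_numpy() < min_maf) & ~chrom_bad
    keep = ~(chrom_bad | maf_bad)
    if not keep.any():
        logger.warning("filter_sites removed every site")
    out = panel.take_sites(np.flatnonzero(keep))
    return FilterResult(out, int(maf_bad.sum()), int(chrom_bad.sum()))


def split_by_population(panel: GenotypePanel) -> dict[str, GenotypePanel]:
    """Partition a panel by population label; sub-panel MAFs are recomputed.

    MAF re-filtering of each sub-panel is the caller's responsibility
    (``filter_sites`` is applied after splitting).
    """
    unlabeled = [s for s in panel.sample_ids if s not in panel.population]
    if unlabeled:
        raise ValueError(f"individuals without population label: {unlabeled}")
    out: dict[str, GenotypePanel] = {}
    for pop in dict.fromkeys(panel.population[s] for s in panel.sample_ids):
        ids = [s for s in panel.sample_ids if panel.population[s] == pop]
        out[pop] = panel.take_individuals(ids).with_fresh_maf()
    return out


def read_population_table(path: str) -> dict[str, str]:
    """Two-column TSV (sample id, population label) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_population_table(population: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for s, p in population.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# QTL table and gene annotation
# ---------------------------------------------------------------------------

def read_qtl_table(path: str) -> list[QtlRecord]:
    """Tab-separated QTL table: chrom, start, end, trait_abbrev, qtl_id.

    Rows with end < start (present in real QTL databases) are skipped
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "trait_abbrev", "qtl_id"],
                     dtype={"chrom": str, "trait_abbrev": str, "qtl_id": str})
    records: list[QtlRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if row.end < row.start:
            n_skipped += 1
            logger.warning("skipping malformed QTL %s: end %s < start %s",
                           row.qtl_id, row.end, row.start)
            continue
        records.append(QtlRecord(row.chrom, int(row.start), int(row.end),
                                 row.trait_abbrev, row.qtl_id))
    return records


def write_qtl_table(qtls: list[QtlRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: chrom\tstart\tend\ttrait_abbrev\tqtl_id\n")
        for q in qtls:
            fh.write(f"{q.chrom}\t{q.start}\t{q.end}\t{q.trait_abbrev}\t{q.qtl_id}\n")


def read_gff3_genes(path: str) -> list[GeneRecord]:
    """Gene features from a GFF3 file (1-based inclusive, as GFF3 itself)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [""])[0]
        genes.append(GeneRecord(feat.seqid, feat.start, feat.end, gene_id, name))
    return genes


def write_genes_gff3(genes: list[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.gene_name:
                attrs += f";Name={g.gene_name}"
            fh.write(f"{g.chrom}\thapblockscan\tgene\t{g.start}\t{g.end}"
                     f"\t.\t+\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Blocks as BED
# ---------------------------------------------------------------------------

def write_blocks_bed(blocks: list[HaploBlock], path: str) -> None:
    """BED (0-based half-open): start - 1, end unchanged."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\tblock{i}\t{b.n_snps}\n")


def read_blocks_bed(path: str) -> list[HaploBlock]:
    """Read BED intervals back as blocks (member SNP indices are not stored)."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            blocks.append(HaploBlock(parts[0], int(parts[1]) + 1, int(parts[2])))
    return blocks


def write_blocks_detail(blocks: list[HaploBlock], panel: GenotypePanel, path: str) -> None:
    """Per-block table: chrom, start, end, length_kb, n_snps, member positions."""
    with open(path, "w") as fh:
        fh.write("# columns: chrom\tstart\tend\tlength_kb\tn_snps\tsnp_positions\n")
        for b in blocks:
            pos = ",".join(str(int(panel.sites.iloc[i]["pos"])) for i in b.snp_indices)
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.length_kb:.3f}"
                     f"\t{b.n_snps}\t{pos}\n")
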