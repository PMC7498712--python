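"""End-to-end orchestration: config -> filtered panels -> reports.

``run_all`` executes the full analysis — site filtering, per-population
LD decay and Ne, haplotype blocks by both definitions, diversity and
distance statistics, cross-population block sharing, top-block
selection, and QTL/gene/enrichment annotation — writing one
tab-separated report per stage into the output directory.  Every
stochastic stage consumes a stage-specific child seed derived from the
run seed, so a fixed seed reproduces the whole bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import blocks as blk
from . import compare as cmp
from . import decay
from . import diversity as div
from . import io as hio
from . import simdata
from .panel import GenotypePanel

logger = logging.getLogger("hapblockscan")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # file-mode inputs
    vcf: str | None = None
    population_table: str | None = None
    qtl_table: str | None = None
    gff3: str | None = None
    term_gmt: str | None = None
    # simulate-mode input
    simulate: dict | None = None
    # stage parameters
    focal_population: str | None = None
    min_maf: float = 0.05
    drop_chroms: list[str] = field(default_factory=lambda: ["Y"])
    max_window_bp: int = 1_000_000
    bin_edges_kb: list[float] = field(default_factory=lambda: list(decay.BIN_EDGES_KB))
    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90
    inform_frac: float = 0.95
    max_span_kb: float = 200.0
    min_hap_freq: float = 0.01
    ne_alpha: float = 2.2
    morgans_per_bp: float = 1e-8
    qtl_max_span_bp: int = 10_000_000
    overlap_min_fraction: float = 0.5
    k_length: int = 10
    k_snps: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        file_mode = self.vcf is not None
        if file_mode == (self.simulate is not None):
            raise ValueError("config must provide exactly one of 'vcf' (file "
                             "mode) or 'simulate'")
        if file_mode and self.population_table is None:
            raise ValueError("file mode requires a population_table")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sim_config(cfg: RunConfig, seed: int) -> simdata.SimConfig:
    spec = dict(cfg.simulate or {})
    pops = [simdata.PopulationConfig(**p) for p in spec.pop("populations")]
    spec.pop("seed", None)
    planted = {c: [tuple(r) for r in rs]
               for c, rs in (spec.pop("planted_block_regions", {}) or {}).items()}
    return simdata.SimConfig(seed=seed, populations=pops,
                             planted_block_regions=planted, **spec)


def load_inputs(cfg: RunConfig):
    """Load or simulate the panel, QTLs, genes and term sets."""
    ss = np.random.SeedSequence(cfg.seed)
    s_panel, s_qtl, s_genes = [int(s.generate_state(1)[0] % 2**31)
                               for s in ss.spawn(3)]
    truth = None
    if cfg.simulate is not None:
        sim = _sim_config(cfg, s_panel)
        panel, truth = simdata.simulate_panel(sim)
        qtls = simdata.simulate_qtl_table(s_qtl, n_qtls=40,
                                          span_range=(50_000, 2_000_000),
                                          chrom_lengths=sim.chrom_lengths,
                                          frac_large=0.25)
        genes = simdata.simulate_genes(s_genes, n_genes=60, chrom_lengths=sim.chrom_lengths)
        rng = np.random.default_rng(s_genes)
        ids = [g.gene_id for g in genes]
        terms = {f"TERM{k}": {g for g in ids if rng.random() < 0.2}
                 for k in range(8)}
        terms = {t: g for t, g in terms.items() if g}
    else:
        populations = hio.read_population_table(cfg.population_table)
        panel = hio.read_vcf(cfg.vcf, populations)
        qtls = hio.read_qtl_table(cfg.qtl_table) if cfg.qtl_table else []
        genes = hio.read_gff3_genes(cfg.gff3) if cfg.gff3 else []
        terms = ann.read_gmt(cfg.term_gmt) if cfg.term_gmt else {}
    return panel, qtls, genes, terms, truth


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the in-memory result bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.to_yaml(str(out / "run_config.yaml"))

    panel, qtls, genes, terms, truth = load_inputs(cfg)

    # site filtering on the joint panel (shared-site view for Fst/distance),
    # then per-population split and re-filter, matching the study's order
    joint = hio.filter_sites(panel, cfg.min_maf, set(cfg.drop_chroms)).panel
    shared = hio.split_by_population(joint)
    pops: dict[str, GenotypePanel] = {}
    for pop, sub in hio.split_by_population(panel).items():
        pops[pop] = hio.filter_sites(sub, cfg.min_maf, set(cfg.drop_chroms)).panel

    results: dict = {"populations": list(pops)}

    # --- LD decay and Ne ---------------------------------------------------
    fits, ne_traj, binned_tables = {}, {}, {}
    for pop, sub in pops.items():
        obs = [decay.pairwise_ld(sub, c, cfg.max_window_bp)
               for c in sub.chromosomes()]
        import pandas as pd
        allobs = pd.concat(obs, ignore_index=True) if obs else None
        binned = decay.bin_ld(allobs, cfg.bin_edges_kb)
        binned_tables[pop] = binned
        decay.write_decay_table(binned, str(out / f"ld_decay_{pop}.tsv"))
        try:
            fits[pop] = decay.fit_sved(binned)
        except ValueError:
            fits[pop] = None
        ne_traj[pop] = decay.estimate_ne(binned, sub.n_individuals,
                                         alpha=cfg.ne_alpha,
                                         morgans_per_bp=cfg.morgans_per_bp)
        decay.write_ne_table(ne_traj[pop], str(out / f"ne_{pop}.tsv"))
    results["decay_fits"] = fits
    results["ne"] = ne_traj
    results["binned_ld"] = binned_tables

    # --- blocks -------------------------------------------------------------
    gabriel: dict[str, list] = {}
    fourg: dict[str, list] = {}
    for pop, sub in pops.items():
        gabriel[pop] = [b for c in sub.chromosomes()
                        for b in blk.gabriel_blocks(
                            sub, c, cfg.strong_low, cfg.strong_high,
                            cfg.recomb_high, cfg.inform_frac, cfg.max_span_kb,
                            cfg.min_maf)]
        fourg[pop] = [b for c in sub.chromosomes()
                      for b in blk.four_gamete_blocks(sub, c, cfg.min_hap_freq)]
        hio.write_blocks_bed(gabriel[pop], str(out / f"blocks_gabriel_{pop}.bed"))
        hio.write_blocks_bed(fourg[pop], str(out / f"blocks_fourgamete_{pop}.bed"))
        summary = blk.block_summary(gabriel[pop], sub)
        blk.write_block_summary(summary, str(out / f"table2_blocks_{pop}.tsv"))
    results["gabriel_blocks"] = gabriel
    results["four_gamete_blocks"] = fourg

    # --- diversity (table 1) -------------------------------------------------
    with open(out / "table1_diversity.tsv", "w") as fh:
        fh.write("# columns: population\tn_blocks\tmean_hap_frequency"
                 "\tmean_hap_diversity\n")
        table1 = {}
        for pop, sub in pops.items():
            bl = gabriel[pop]
            if bl:
                spectra = [div.block_spectrum(sub, b) for b in bl]
                freq, divr = div.breed_block_summary(spectra)
            else:
                freq, divr = float("nan"), float("nan")
            table1[pop] = (len(bl), freq, divr)
            fh.write(f"{pop}\t{len(bl)}\t{freq:.4f}\t{divr:.4f}\n")
    results["table1"] = table1

    # --- distances ------------------------------------------------------------
    dist = div.ibs_distance(joint)
    div.write_matrix(dist, str(out / "distance_1_minus_dst.tsv"))
    fst = div.pairwise_fst(shared) if len(shared) >= 2 else None
    if fst is not None:
        div.write_matrix(fst, str(out / "fst_matrix.tsv"))
    results["distance"] = dist
    results["fst"] = fst

    # --- sharing (table 3) -----------------------------------------------------
    if len(gabriel) >= 2:
        sharing = cmp.sharing_matrix(gabriel)
        div.write_matrix(sharing.round(2), str(out / "table3_sharing.tsv"))
        results["sharing"] = sharing
        results["multiway_shared_bp"] = cmp.multiway_shared_length(
            gabriel, list(gabriel))

    # --- annotation (tables 4-5) ----------------------------------------------
    focal = cfg.focal_population or next(iter(pops))
    focal_blocks = gabriel[focal]
    results["focal"] = focal
    if focal_blocks:
        selected = blk.select_top_blocks(focal_blocks, cfg.k_length, cfg.k_snps)
        sel_blocks = [s.block for s in selected]
        kept_qtls, n_removed = ann.filter_qtls(qtls, cfg.qtl_max_span_bp)
        hits = ann.block_qtl_overlap(sel_blocks, kept_qtls,
                                     cfg.overlap_min_fraction)
        ann.write_qtl_hits(hits, str(out / "table4_qtl.tsv"))
        gene_map = ann.map_genes(sel_blocks, genes)
        gene_list = sorted({g.gene_id for gl in gene_map.values() for g in gl})
        background = [g.gene_id for g in genes]
        enrich = (ann.ease_enrichment(gene_list, terms, background)
                  if terms and gene_list else [])
        ann.write_enrichment(enrich, str(out / "table5_enrichment.tsv"))
        results.update(selected=selected, qtl_hits=hits,
                       n_qtls_removed=n_removed, gene_map=gene_map,
                       enrichment=enrich)
    if truth is not None:
        results["truth"] = truth
    logger.info("run complete: %s", out)
    return results
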