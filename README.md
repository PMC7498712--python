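# hapblockscan

Linkage-disequilibrium and haplotype-block analysis for multi-population
SNP panels, written for livestock population genetics (the conventions
follow pig-breed panel studies, but nothing is species-specific).

Given phased biallelic genotypes for several populations, the package

* estimates pairwise LD (r²) within a 1 Mb window, averages it in the
  standard distance bins (0–10, 10–20, 20–40, 40–60, 60–100, 100–200,
  200–500, 500–1000 kb), and fits the hyperbolic decay model
  *r²(d) = 1 / (1 + 4βd)*;
* converts distance-binned r² into an effective-population-size
  trajectory through *E(r²) = 1 / (α + 4N_e c)* with the generation
  mapping *t = 1/(2c)* (default map: 100 Mb = 1 Morgan; α = 2.2 with
  the mutation correction enabled, sample-size correction 1/(2n));
* detects haplotype blocks two ways: Gabriel-criteria blocks (pairs
  classified from the D′ confidence interval — strong LD when
  CI ⊆ [0.70, 1] with upper bound ≥ 0.98, strong recombination when the
  upper bound < 0.90 — with ≥ 95 % informative pairs in strong LD and a
  200 kb span cap) and four-gamete blocks (a block ends where a pair of
  member SNPs shows all four gametes at frequency ≥ 0.01);
* summarises blocks per chromosome (counts, lengths, SNPs per block,
  percent of SNPs clustered into blocks) and haplotype diversity
  *H = 1 − Σ fᵢ²* per block and per population;
* computes individual genetic distances *1 − Dst* with
  *Dst = (IBS₂ + 0.5·IBS₁)/N*, and pairwise Weir–Cockerham F_ST between
  populations;
* compares block sets across populations (percent of a focal
  population's blocks overlapping a partner's, population-unique blocks,
  multi-way shared length);
* annotates the top blocks (top 10 by length plus top 10 by SNP count)
  against a QTL table (spans ≤ 10 Mb, hit when the overlap exceeds 50 %
  of the shorter feature) and a gene annotation, with EASE-score
  (hit-cell-reduced one-sided Fisher) term enrichment under
  Benjamini–Hochberg FDR.

A synthetic-data module simulates multi-population phased panels with
known LD decay, planted recombination-free segments and known N_e, so
the whole pipeline is testable end to end without external data.

## Worked example

```python
from hapblockscan import (SimConfig, PopulationConfig, simulate_panel,
                          split_by_population, filter_sites, pairwise_ld,
                          bin_ld, fit_sved, estimate_ne, gabriel_blocks,
                          block_spectrum, breed_block_summary, pairwise_fst)

cfg = SimConfig(
    seed=42,
    populations=[PopulationConfig("JQ", 25, n_founders=10, ne_true=100),
                 PopulationConfig("HB", 25, n_founders=10, ne_true=100)],
    chrom_lengths={"1": 2_000_000},
    site_density=0.4,          # expected SNPs per kb
    recomb_rate=1e-6,          # crossovers per bp per meiosis
    n_generations=120,
)
panel, truth = simulate_panel(cfg)
print(f"panel: {panel.n_individuals} individuals, {panel.n_sites} SNPs")

pops = {p: filter_sites(s, min_maf=0.05).panel
        for p, s in split_by_population(panel).items()}
jq = pops["JQ"]
binned = bin_ld(pairwise_ld(jq, "1", max_window_bp=1_000_000))
print(binned.round(3).to_string(index=False))

fit = fit_sved(binned)
print(f"decay coefficient beta = {fit.beta:.4f} per kb")

ne = estimate_ne(binned, jq.n_individuals, morgans_per_bp=1e-6)
for p in ne[2:5]:
    print(f"t = {p.t:>3} generations ago: Ne = {p.ne:.0f}")

blocks = gabriel_blocks(jq, "1")
freq, div = breed_block_summary([block_spectrum(jq, b) for b in blocks])
print(f"{len(blocks)} Gabriel blocks; mean haplotype frequency {freq:.2f}, "
      f"diversity {div:.3f}")

shared = split_by_population(filter_sites(panel, 0.05).panel)
print(f"Fst(JQ, HB) = {pairwise_fst(shared).loc['JQ', 'HB']:.3f}")
```

Output:

```
panel: 50 individuals, 506 SNPs
 bin_lo_kb  bin_hi_kb  mean_r2  n_pairs
       0.0       10.0    0.379      418
      10.0       20.0    0.208      385
      20.0       40.0    0.121      757
      40.0       60.0    0.077      766
      60.0      100.0    0.042     1482
     100.0      200.0    0.031     3347
     200.0      500.0    0.028     9340
     500.0     1000.0    0.023    11581
decay coefficient beta = 0.0732 per kb
t =  17 generations ago: Ne = 65
t =  10 generations ago: Ne = 77
t =   6 generations ago: Ne = 132
50 Gabriel blocks; mean haplotype frequency 0.36, diversity 0.495
Fst(JQ, HB) = 0.548
```

Reading the output: mean r² falls from 0.38 for SNPs closer than 10 kb
to 0.02 beyond 500 kb — the fitted β of 0.073 per kb summarises that
decay.  Inverting the binned r² gives N_e estimates of roughly 65–130
across the recent generations, bracketing the simulated N_e of 100
(the `morgans_per_bp` argument matches the simulated crossover rate).
The two populations were founded from independent haplotype pools, so
F_ST is large.

## Command line

```sh
hapblockscan run-all --config run.yaml --seed 7 --out results/
```

runs every stage (filter → split → LD decay + Ne → blocks by both
definitions → diversity, distances, F_ST → sharing → top-20 selection →
QTL/gene/enrichment) and writes one tab-separated report per stage
(`table1_diversity.tsv` … `table5_enrichment.tsv`, decay and Ne tables,
block BEDs, distance/F_ST matrices).  The config is YAML with either a
`simulate:` section or file-mode inputs (`vcf`, `population_table`,
`qtl_table`, `gff3`, `term_gmt`); `hapblockscan simulate` writes a full
set of simulated input files, and the stage subcommands (`ld`, `ne`,
`blocks`, …) run stages independently.  Re-running from the serialized
`run_config.yaml` reproduces the bundle byte for byte.

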