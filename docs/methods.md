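# Methods

## Data model and conventions

The unit of analysis is a phased panel: a matrix of 0/1 alleles with two
rows per diploid individual, site metadata (chromosome, 1-based
position, alleles, minor allele frequency) and a population label per
individual.  All genomic intervals are 1-based and inclusive, and an
interval's length is `end − start + 1` bp — so a block of two adjacent
SNPs has length 2 bp (0.002 kb).  BED files are converted to and from
this convention at the IO boundary.  Missing or unphased genotypes are
rejected rather than imputed: phasing and imputation belong upstream of
this package.  Site filtering keeps sites with MAF ≥ the threshold
(inclusive, default 0.05) and is applied per population after
splitting, mirroring the usual order in breed-panel studies; the joint
panel is filtered once more for the shared-site analyses (distance and
F_ST) so that all populations see the same loci.

## Two-locus LD

r² and D′ are computed from phased haplotype counts.  For counts
(n_AB, n_Ab, n_aB, n_ab): D = p_AB − p_A·p_B, D′ = |D|/D_max with D_max
the frequency-bound extreme of D in the direction of the observed D,
and r² = D²/(p_A(1−p_A)p_B(1−p_B)).  An EM routine is provided for
unphased genotype input (the only ambiguous cell is the double
heterozygote; convergence at a max frequency change < 1e−8 or 1000
iterations), but phased counting is the default path since the intended
input is phased.

The D′ confidence interval follows the likelihood-grid construction
used by Gabriel-style block callers: the multinomial likelihood of the
observed counts is evaluated at 101 equally spaced D′ values in [0, 1]
with allele frequencies fixed at their observed values and D signed
toward the observed D; after normalising the grid to sum to one, the
lower bound is the smallest grid value where the cumulative mass
exceeds 0.05 and the upper bound the smallest where it exceeds 0.95.
Ties at grid boundaries resolve to the smaller index, which is the
conservative choice for the lower bound.  Pairs are then classified as
strong LD (lower ≥ 0.70 and upper ≥ 0.98), strong recombination
(upper < 0.90) or uninformative.

## Haplotype blocks

Gabriel blocks: all pairs within the span cap (default 200 kb,
configurable; chosen to match the common default of the tools used for
such panels) are classified as above; a candidate interval requires its
outermost pair to be strong LD and the fraction of strong-LD pairs
among its informative internal pairs to be ≥ 0.95; candidates are
accepted greedily by descending physical span (ties by leftmost start)
without sharing markers.  The marker-count-dependent special cases that
some implementations apply to very short candidates are deliberately
not implemented — uniform criteria apply to all pair spans — because
they are tool-internal details rather than part of the published
definition.  Sites below the MAF threshold are excluded from pairing.

Four-gamete blocks: a greedy left-to-right scan grows a block while
every pair of member sites shows at most three of the four two-locus
gametes at frequency ≥ 0.01 (inclusive); a fourth gamete at that
frequency marks a historical recombination event and closes the block
at the previous site.  Only blocks with ≥ 2 SNPs are reported.

Per-chromosome summaries report block counts, total/mean/min/max block
length, SNPs per block, and the percentage of SNPs in blocks, where the
percentage column is relative to all SNPs clustered into blocks (so it
sums to 100 across chromosomes) and the grand-total mean block size is
the unweighted mean of the per-chromosome means — these aggregation
rules are pinned by the acceptance tests against a published
per-chromosome block table.

## LD decay and N_e

Observed r² at physical distance d (kb) is modelled as
r² = 1/(1 + 4βd) + e; β is fitted by bounded nonlinear least squares
(trust-region reflective, tolerances 1e−12), either to raw pairs or to
bin means, and the fitted curve is reported on the conventional
distance grid (0, 4, 8, …, 1000 kb).  The fit is exact on noiseless
data and is cross-checked in the tests against a dense grid search.

The N_e trajectory inverts E(r²) = 1/(α + 4N_e c) per distance bin:
c is the recombination fraction of the bin midpoint under a
physical-to-genetic map (default identity at 1e−8 Morgans/bp, i.e.
100 Mb = 1 Morgan; a Haldane map is available and the mapping is
pluggable because published trajectories differ in the recombination
modifier they apply), t = 1/(2c) rounded to the nearest generation,
and the sample-size correction subtracts 1/(2n) from the bin mean
before inversion.  α defaults to 2.2 (mutation correction on);
α = 1 gives the textbook drift-only inversion, which the tests verify
is exact on synthetic points placed on the curve.  Bins whose corrected
r² is incompatible with a positive N_e (r²_adj ≥ 1/α) are dropped with
a warning — with small samples and strong LD this is common at short
distances and is a property of the estimator, not an error.

## Diversity, distance and differentiation

Haplotype diversity of a block is 1 − Σ fᵢ² over the frequencies of its
distinct haplotype strings.  The population-level "haplotype frequency"
is the mean over blocks of the block's mean haplotype frequency, which
equals 1/k for a block with k distinct haplotypes — this interpretation
reproduces the magnitude (~0.25–0.36) seen in published per-breed
tables alongside ~4.5 SNPs per block; the alternative (frequency of the
major haplotype) would be systematically higher.  Both population
statistics are unweighted means over blocks.

Individual distance is 1 − Dst with Dst = (IBS₂ + 0.5·IBS₁)/N over all
loci.  Population differentiation is the Weir & Cockerham (1984)
two-population θ, accumulated as a ratio of sums over loci; the
estimator is verified against an independent per-locus scalar
implementation to 1e−10 and calibrated on simulations (≈0 under
panmixia, 1 under fixation).

## Cross-population comparison

Sharing between populations is counted block-wise: entry (r, c) is the
percentage of r's blocks overlapping any block of c by ≥ 1 bp.  This is
intentionally asymmetric — a block-poor population shares a small
fraction of a block-rich partner's set — which matches the asymmetry
pattern of published sharing tables; a length-weighted variant is
available behind a flag.  Multi-way shared length is the total base
count covered by the merged block set of every member population,
computed by an endpoint sweep and verified against a per-base
membership oracle.

## Annotation

QTLs with spans above 10 Mb (inclusive boundary at exactly 10 Mb) are
discarded before overlap testing, then a block/QTL pair is a hit when
the overlap exceeds half the length of the shorter feature — strictly,
so an exact 50 % overlap is not a hit.  Using the shorter feature as
the denominator makes the rule symmetric and implies that containment
of either feature in the other always qualifies.  Genes map to blocks
on any ≥ 1 bp overlap.  Enrichment uses the EASE score: the one-sided
Fisher exact p of the 2×2 table with one hit removed from the overlap
cell, computed as the hypergeometric tail P(X ≥ k−1) — identical to the
reduced-table Fisher p but well-defined at boundary margins — so a
single-gene hit scores p = 1 by construction.  Term databases are
user-supplied GMT files; there is no remote database access, because
term-count results depend on database versions and are not
reproducible otherwise.  Benjamini–Hochberg FDR is computed across the
tested terms.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes:
several populations of phased diploids, sites with post-filter
MAF ≥ 0.05, LD that decays with distance, planted recombination-free
segments, and known per-population N_e.

Founder haplotypes are drawn under a perfect phylogeny: each site's
derived allele is assigned to one clade of a random binary genealogy
over the founders, so the founder set never exhibits all four gametes
for any pair of sites — a recombination-free genome is therefore
four-gamete consistent by construction, which is what makes planted
blocks a usable ground truth.  The founders seed a Wright–Fisher
population of 2·N_e haplotypes; each generation every haplotype is a
recombinant mosaic of two random parents with crossover probability
1 − exp(−recomb_rate·gap) per inter-site gap, forced to zero for gaps
intersecting a planted region.  This drift–recombination process drives
r² toward 1/(1 + 4N_e c), so the decay fit and the N_e inversion have a
meaningful truth to recover.  Sampled haplotypes are optionally
mutated (independent allele flips) and sites below 0.05 panel-wide MAF
are dropped, mirroring the ascertainment of the retained panels the
analysis targets.

Default study conditions: four populations of 20 diploid individuals,
chromosomes of 1–2 Mb, 0.4 expected SNPs per kb, N_e of order 100,
crossover rate 1e−8–1e−6 per bp, ~100 generations.  These sizes keep a
full end-to-end run in seconds while leaving hundreds of post-filter
sites per chromosome.  What the generator does **not** emulate: genome-
scale chromosome counts and site densities, mutation–drift equilibrium
(panels start from a founder bottleneck, so very recent N_e estimates
reflect the founder pool as much as the nominal N_e), X-chromosome
dosage, selection, and cross-population admixture (founder pools are
independent, so simulated F_ST is high and block sharing reflects
chance overlap).  Passing tests therefore demonstrate the correctness
of the statistics and the recoverability of planted structure, not
calibration against real pig panels.

## Numerical and design choices

* All stochastic operations take explicit integer seeds; the pipeline
  derives stage-specific child seeds from the run seed, making report
  bundles byte-identical across re-runs.
* The bin table is left-open/right-closed in kb; observations beyond
  the last edge are excluded and counted.
* The Gabriel caller's greedy acceptance orders candidates by physical
  span descending with ties broken by leftmost start; accepted blocks
  never share markers.
* `fit_sved` refuses distance sets that cannot identify β (all
  observations at d = 0).
* Degenerate D′ likelihoods (all mass at one grid point) collapse the
  CI to that point; a 2-point grid yields endpoints in {0, 1}.
* Empty inputs degrade softly where the quantity is defined (empty
  block lists, empty LD streams) and raise where it is not
  (monomorphic loci in two-locus statistics, fewer than two
  populations for F_ST).

## Known limitations

* The Gabriel criteria are applied uniformly to all pair spans; callers
  that special-case short blocks will produce slightly different block
  sets on the same data.
* The four-gamete scan checks every pair within the growing block
  (not just adjacent pairs), which is stricter than some
  implementations for long blocks.
* N_e estimates at very short distances (old generations) are biased by
  MAF ascertainment and the founder bottleneck of the simulator; the
  mid-distance bins are the reliable regime, and the tests assert
  factor-two recovery there on coalescent simulations.
* The per-population split recomputes MAF but the sharing analysis
  compares block coordinates only; blocks are not re-phased or
  re-called on merged panels.
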