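# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `promethyl`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinates and design

All internal coordinates are 0-based, half-open; 1-based formats (GFF3,
Bismark coverage) are converted at the I/O boundary and back on write. CpG
sites are keyed by the '+'-strand cytosine position after strand merging
(merging itself is upstream of this package). Promoter-local coordinates
are signed bp from the TSS, negative upstream, strand-aware; the promoter
is the fixed span [−2000, +200) and the TSS base itself is rel 0 (the
downstream side). The experiment design is 2 genotypes (growth-modified
"transgenic" vs "non_transgenic") × 3 time points (Day0 fed, Day28
feed-deprived, Day41 re-fed) × 2 replicate pools, and the nine standard
contrasts are the six within-genotype time contrasts plus the three
between-genotype contrasts; effects are always reported as B − A (so
"hyper" / "up" mean higher in the second-named group).

## Differential methylation

Units are CpG sites, tiled promoter windows, or whole promoters. Sites must
have ≥ `min_coverage` (default 10) reads in **every** pool; coverage is then
normalized by scaling each pool's counts by
median(pool medians)/median(pool i), rounding half-up on both counts
independently, which preserves each site's methylation fraction to within
one read (property-tested).

The test is a binomial logistic regression logit(p) = β₀ + β₁·group over
the pools' (methylated, coverage) observations. With one two-level factor
the MLE is closed-form — each group's fitted probability is its
coverage-pooled proportion — so the genome is tested with array
arithmetic; unit tests verify the likelihood-ratio statistic against an
iterative GLM fit to 1e-6. Overdispersion is handled by scaling the LRT by
φ̂ = max(1, Pearson X²/df) of the fitted model (df = pools with coverage −
2) before the χ²₁ p-value. The floor at 1 makes the corrected p
conservative by construction even for perfectly binomial data
(E[max(1, X²/df)] > 1); calibration is therefore asserted on the
uncorrected LRT p-values, while the corrected test is asserted to have a
false-positive rate no larger than the uncorrected one under beta-binomial
noise. Degenerate separation (a group proportion of exactly 0 or 1) is
handled by clipping each group's fitted logit to ±10, which caps the group
coefficient at |β₁| ≤ 20 and keeps the test exactly symmetric under
relabeling A↔B (property-tested). Units with an all-zero-coverage group
are skipped with a logged reason.

Multiple testing is Benjamini–Hochberg, applied genome-wide (whether the
original analysis adjusted genome-wide or per-chromosome is not knowable
from the outside; genome-wide is the conservative, reproducible choice).
Promoter-mode calls require q < 0.01 **and** |Δmeth| ≥ 25 percentage
points; window mode uses p < 0.05 with no effect-size filter, matching the
deliberately more permissive window-scan convention. Δmeth is the
difference of coverage-weighted pooled group percentages.

## Windows

Window sizes 100/50/25/12.5 bp tile [−2000, +200) into exactly
22/44/88/176 windows. The 12.5 bp case uses half-bp integer arithmetic
(window index = (2·(rel+2000)) // 25), so assignment is exact and no
fractional genomic coordinate ever materializes. Aggregation sums member
CpG counts per window per pool; empty windows are excluded from testing
(a test on zero coverage is undefined), and the per-gene sum over windows
of any size equals the whole-promoter aggregate exactly (tested per gene
and size). CpGs inside two overlapping promoters are duplicated, one copy
per gene. Windows are tested per gene per window (a gene can contribute
several DMRs), and positional profiles count significant windows per
relative start.

## Differential expression

An original implementation of the standard count workflow, targeting
statistical agreement rather than bit-compatibility with any reference
tool: genes are kept if CPM ≥ 1 in at least (smallest group size) pools;
TMM factors trim 30% of the log-ratio tails and 5% of the abundance tails
and weight surviving log-ratios by inverse asymptotic variance, with the
reference pool chosen by the upper-quartile rule (smallest index on ties)
and factors rescaled to geometric mean 1 (verified against an independent
brute-force implementation at 1e-6, and loosely against the Bioconductor
implementation). log2-CPM uses a library-size-scaled prior count
(default 2).

NB dispersion: the common value maximizes the Cox–Reid-adjusted profile
log-likelihood (adjustment −½·log Fisher information per fitted group
mean — without it the two-replicate design underestimates φ by roughly a
factor of two) summed over genes on a 61-point log grid over [1e-4, 10]
with golden-section refinement; tagwise values shrink each gene's grid MLE
toward the common value with a prior weight of 10 residual df. The
"robust" behaviour of reference tools is approximated by this shrinkage
only — no outlier down-weighting. Group means are fitted by
Fisher scoring on the log scale with library-size offsets, vectorized over
genes. The DE test is the LRT between one- and two-rate fits with the
gene's tagwise φ, χ²₁ p-values, BH-FDR and calls at FDR < 0.05; fold
changes are reported with a half-count continuity floor.

## Association analyses

* **Metaplot**: each CpG is assigned to the closest TSS (ties by genomic
  position order), kept within [−5000, +1000], binned at 25 bp and
  averaged with coverage weights; an optional centred 5-bin moving average
  stands in for a GAM-type smoother (the package deliberately avoids GAM
  fitting). Trough location/level are read off the smoothed curve.
* **Static association**: OLS of log2-CPM on promoter methylation percent
  over genes with both values, with the two-sided slope t-test and a
  binned 2-D density table for plotting.
* **Change–change association**: per window position, OLS of the DE log2
  fold change on the window's Δmeth across genes; windows with < 10 genes
  or a constant regressor are skipped. Significance tiers are 0.05/0.01/
  0.001 (a display convention); no multiple-testing correction across
  windows by default (a BH option exists behind a flag).
* **Overlap**: a gene overlaps if it is a DEG and has ≥ 1 significant DM
  unit; positional overlap profiles count every significant window of an
  overlapping gene.
* **Derived ratios**: pure integer arithmetic on count tables in the
  standard layouts, with per-field rounding rules (transcript percentages
  to 2 decimals; DEG-overlap percentage to 1 decimal; DMR-overlap and
  up/down/hypo shares to the nearest integer; fold ratios to 1 decimal);
  zero denominators yield NA.

## The generator

`simulate_annotation` places genes every 15 kb (≥ the 6 kb metaplot span,
so spans never overlap) on one synthetic chromosome with random strand.
CpGs are laid down with exponential spacing (mean 30 bp) across each
gene's −5000..+1000 span, plus a sparse strictly-intergenic background
(mean spacing 500 bp) at plateau methylation. Per site and pool, coverage
is Poisson(15) — the middle of a realistic 12–20× WGBS range — and
methylated reads are Binomial(coverage, f) with f drawn Beta with mean μ
and correlation ρ = 0.02 across pools (pooled biological samples imply
extra-binomial variance; this gives the overdispersion correction
something to correct). μ follows a smooth TSS profile: plateau 0.80 far
upstream, monotone descent to a minimum of exactly 0.15 at +200 bp, and
partial recovery into the gene body (to 70% of the plateau–trough range);
profile width 400 bp. Each gene also receives a constant profile offset
~N(0, 0.15) (clipped), emulating the wide between-gene spread of promoter
methylation levels seen in real liver data — without it every simulated
gene would sit at the same promoter level and a static
methylation–expression association would be structurally undetectable.

Treatment effects: a `dm_fraction` of genes get a ±`dm_effect` (30) point
shift over one promoter-local region (default width 100 bp, random
position, or pinned via `dm_region_start`) in all Day28/Day41 pools, so
the six time contrasts carry signal and the three genotype contrasts are
null. Expression is NB (φ = 0.1) with per-pool depth factors U(0.8, 1.2)
and per-gene baselines log2 ~ N(7.5, 2). A `coupling_fraction` of genes
follow log2 μ = baseline + slope·(promoter methylation % − 50), slope
default −0.04 log2 per point (a free parameter — no quantitative coupling
slope is available to match); a coupled gene that also carries a treatment
shift additionally responds at full strength (slope × `dm_effect`),
modelling a regulatory element inside the shifted region rather than an
effect diluted over the whole 2.2 kb promoter — this is what makes
window-local change–change coupling detectable and localizable. A disjoint
`de_fraction` of genes get an independent ±2 log2 shift at the later time
points. All truth tables list exactly the perturbed genes. Every stage
draws from `numpy.random.default_rng([seed, stage_constant])`, so stages
are independently reproducible and the dataset is a pure function of the
seed.

What the generator does **not** emulate: CpG islands, non-CpG contexts,
bisulfite conversion error, read-level artifacts, chromosome structure,
correlated neighbouring CpGs beyond the shared gene offset, or
genotype-specific baselines. Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated model, not
performance on real sequencing data.

## Problem sizes and thresholds in the test suite

Simulation-based checks use 25–2000 genes, chosen so each check has the
statistical resolution it needs: uniformity (KS) checks run near 2–2.5k
units because count-based p-values carry an irreducible discreteness
distance from U(0, 1) that a KS test at much larger n would always detect;
the dm-null calibration uses a homogeneous methylation level (no per-gene
offsets) so near-saturated sites do not contribute degenerate p = 1 atoms.
Recovery checks assert sensitivity floors frozen from a reference run at
the same seeds (observed value minus three binomial standard errors). The
full default pipeline (2000 genes, nine comparisons, all four window
sizes) completes in about a minute on one CPU.

## Known limitations

* The overdispersion treatment is statistic scaling with a χ² reference,
  not an F-test or exact beta-binomial likelihood; with two pools per
  group φ̂ is noisy and the floor at 1 makes corrected p-values
  conservative.
* `estimate_dispersion` has no outlier-robust down-weighting; a single
  aberrant gene inflates its tagwise value but not its neighbours'.
* The metaplot smoother is a moving average, which slightly widens and
  lifts the trough relative to the underlying profile.
* Between-genotype contrasts share one simulated baseline; the generator
  cannot currently plant genotype-specific effects.
* Closest-gene assignment for the metaplot uses distance to TSS with ties
  broken by position order, which for identical-TSS genes reduces to
  lowest gene_id.
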