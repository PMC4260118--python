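# Methods

`haplodrift` characterises the genetic management of outbred laboratory
populations of haplodiploid insects: how fast a given propagation scheme
loses variation (drift simulation), how much drift a genotyped panel has
actually recorded (temporal ABC estimation of Ne), and how diversity is
summarised from marker panels and pooled resequencing. This note
documents the models, the defaults and the numerical choices.

## Temporal differentiation F_t

All drift calibration runs through the temporal differentiation
statistic of Nei & Tajima. For an allele with frequency `x` in the
founding population and `y` at generation `t`,

    f = (x - y)^2 / ((x + y)/2 - x*y)

and `F_t` is the mean of `f` over all alleles of all loci. Alleles
identically fixed or identically absent at both time points have a zero
denominator and are skipped; all other alleles contribute individually
(a locus with k segregating alleles contributes k terms). Under pure
drift the biallelic expectation is

    E[F_t] = 1 - (1 - 1/(2*Ne))^t,

which `ne_from_ft` inverts to give an effective size. Two properties of
the per-allele average matter in practice and are visible in the tests:

* for biallelic loci the simulated mean `F_t` matches the closed form
  closely (the drift-calibration test reproduces it within a few
  percent at `Ne=50, t=32`);
* loci with k > 2 alleles saturate below 1 as fixation becomes common
  (a fixed k-allele locus contributes at most `4/k * sum x(1-x)`), so
  multiallelic panels under strong drift sit 10–25% below the biallelic
  expectation. The closed form is therefore used as an oracle only in
  the biallelic regime; the ABC estimator never relies on it, because
  its forward model measures `F_t` the same way as the data.

## Breeding-scheme drift simulator

The simulator follows a single biallelic locus through a population
kept in `n_tubes` culture tubes with `N_f` mated females per tube.
Females are diploid; males are haploid and develop from unfertilized
eggs, so each carries one maternal allele. One cycle per tube:

1. the resident females produce `round(r * N_f)` sons (random mother,
   one random maternal allele each; pool size has a floor of one male)
   and `N_f` daughters (one random allele of a random mother, plus the
   allele of a father drawn with replacement from the tube's males);
2. with several tubes, all offspring are pooled and redistributed in
   equal numbers to fresh tubes before they reproduce — the mixing step
   that keeps parallel tubes one population;
3. the census allele frequency is taken over female gene copies (two
   per female), matching panels that genotype females; a switch adds
   the males' single copies.

Fathers are independent draws per daughter (random union of gametes).
This is the mating model under which the classical haplodiploid
prediction

    Ne = 9 * N_f * N_m / (2 * N_f + 4 * N_m)

applies, and the simulator reproduces it: at `N_f = N_m = 120` the
prediction is 180 and 20 000-replicate runs land within a few percent,
for the four-tube and the single-tube layout alike. A documented
`monogamous=True` switch instead mates each female to a single male so
that broods share a father; because offspring that share a mother then
always share a father, this roughly halves the effective number of
males (measured: Ne ≈ 133 instead of ≈ 176 at r = 1) and is provided
for comparing husbandry regimes.

Founding females and males are initialised at exactly `p0` (balanced
assignment, shuffled within replicates), not by Bernoulli draws:
`F_t` measures variance accumulated *since* founding, and random
founders would add one spurious generation of sampling variance (about
a 3% downward bias on Ne at t = 32).

Defaults: `p0 = 0.5` (maximises the drift signal; the standardised
`F_t` is approximately invariant to `p0` in expectation), `r = 1.0`.
`hvrx_config()` is a preset for the wasp culture the package grew out
of — four tubes of 30 (or one of 120) mated females, 32 generations,
and `r = 0.89`, the male:female ratio at which the closed form predicts
Ne = 173 for the 120-female census. Simulation means use 10 000–20 000
replicates; quadrupling that changes the Ne estimate by well under a
percent but dominates runtime.

## ABC estimation of realized Ne

The estimator conditions on three summary statistics per observation
generation — mean alleles per locus, mean unbiased expected
heterozygosity, and `F_t` against the base population — observed by
default at generations 5, 10 and 32 (nine summaries). The forward
model is a *diploid* Wright–Fisher population: proposals `Ne ~ U(0,
1000)` (rounded, floor 2), each locus's base frequencies resampled as a
multinomial of `2*Ne` gene copies per generation, and a multinomial
sample of `2n` gene copies taken at each observation generation
(defaults n = 24). The estimated quantity is therefore "diploid
individuals", a deliberate simplification for a haplodiploid organism:
the drift recorded by a female-genotyped panel is summarised on the
diploid scale the formula-free estimator needs no correction for.

A proposal is accepted when `|S - O| / O < ε` for every element
(default ε = 0.11). Two operational choices:

* observations equal to zero make the relative distance undefined; the
  sampler then refuses to run and points to the absolute-distance
  switch rather than silently dividing by zero;
* instead of fixing ε, `target_rate` tunes it to the empirical distance
  quantile that accepts the requested fraction (the package's tests use
  0.005 on 10^5 iterations, i.e. 500 accepted draws). Desk-scale
  default is 10^5 iterations; the method itself is routinely run at
  10^7 for publication-grade posteriors, which only tightens the
  accepted set.

The posterior mean is the mean of accepted draws; the mode is located
with a Gaussian KDE (Silverman bandwidth) evaluated on a unit grid over
the prior range, which is stable for the few hundred accepted draws the
tuned runs produce. Parameter recovery on synthetic data (truth
Ne = 200, 40 loci) places the posterior mode within ±25% of the truth
in at least nine of ten seeded runs; single runs at the edge of that
band occur, which is the expected dispersion of a nine-summary
statistic over 40 loci, not an estimator bias.

The forward model is vectorised batch-wise (loci grouped by allele
count, all proposals of a batch evolved with one broadcast multinomial
per generation); the batch size only sets vectorisation granularity but
participates in the random stream, so reproducibility is seed +
config + batch size.

## Microsatellite statistics

* Expected heterozygosity: Nei's unbiased gene diversity
  `m/(m-1) * (1 - sum p_i^2)` with `m` the gene-copy count. Its upper
  bound is 1, attained when all `m` copies differ.
* Allelic richness: rarefaction `sum_i [1 - C(M - M_i, g) / C(M, g)]`,
  computed with exact integer binomials; tables rarefy to the smallest
  per-locus gene-copy count across the compared populations, the
  convention for panels genotyped at unequal sample sizes.
* F_ST: Weir & Cockerham's θ from per-allele variance components,
  summed over all alleles and loci before taking the ratio.
  Significance is a permutation test that reassigns whole multilocus
  genotypes to the two populations, with +1 smoothing on both numerator
  and denominator of the p-value; a Bonferroni helper corrects tables
  of pairwise results. θ is undefined (flagged, not NaN-silent) without
  a shared polymorphic locus, and is slightly negative for identical
  samples, as an unbiased estimator must be.
* Missing data: per-locus gene counting, no imputation; loci with all
  calls missing in a population are dropped from its table with a
  warning.

## Pool-seq filtering and windows

Site filtering applies the standard pooled-variant rules — minimum
consensus quality 20, minimum mapping quality 20, coverage within
[8, 10^6], minor-allele read count ≥ 2 — all inclusive at the
threshold. Filtering is idempotent and monotone in every threshold
(property-tested under randomized sweeps).

Windows are nonoverlapping half-open 0-based intervals (default 100 kb;
input positions are 1-based, converted internally; the last window of a
chromosome may be short). Per window: SNP count, mean read depth,
depth-adjusted density `n_snps / mean_depth` (reported only when mean
depth ≥ the coverage floor; per-window ratios are averaged, not a
ratio of averages), the fraction of positions whose depth lies within
the coverage bounds, and nucleotide diversity

    pi = sum_sites (d/(d-1)) * (1 - sum_a (c_a/d)^2) / (qualifying positions),

reported only when the qualifying-coverage fraction reaches 0.6. The
per-site term is a simplified unbiased heterozygosity: it matches the
structure of pooled-pipeline π estimators but not their minor-allele-
count correction terms, so absolute π values are comparable in
magnitude, not bit-exact, with those pipelines. When no per-base depth
track is available, mean depth and the coverage fraction fall back to
the depths of the SNP sites themselves and the π denominator to the
implied number of qualifying positions; this approximation is flagged
per row.

## Synthetic data

The generators define the package's study conditions:

* Founder panels: 40 loci, 2–6 alleles per locus (symmetric Dirichlet,
  concentration 1), rejection-sampled until the panel's mean gene
  diversity falls in [0.45, 0.65] — the diversity regime of a
  moderately polymorphic microsatellite panel (observed means ≈ 0.59
  H_E, ≈ 3.7 rarefied alleles per locus for 24 founders). Allele
  labels are even fragment lengths from 100, semantically opaque.
* Temporal series: pure diploid Wright–Fisher drift from the founder
  frequencies (no mutation — allele sets can only shrink), sampling 24
  diploid females at generations 5, 10 and 32 by default.
* Pool-seq landscapes: five chromosomes (0.5–0.7 Mb, 3 Mb total —
  a hundredfold scale-down of a parasitoid genome so window analyses
  run in seconds), genome-average SNP density 2×10⁻³/bp (≈ 200 per
  100-kb window), SNP intensity rising quadratically towards chromosome
  tips (default tip:centre ratio 3), negative-binomial read depth
  (mean 45, dispersion 8) whose mean dips to 0.7× at the chromosome
  centre, uniform minor-allele frequencies on [0.05, 0.5], and normal
  quality scores placing a small tail below the filter thresholds.
  Positions where the depth track falls below 2 reads drop their
  candidate SNPs, reproducing the empty-π windows of low-coverage
  pericentromeric regions.

What these emulations do *not* carry over from real data: mutation,
selection, linkage between loci, allele-frequency spectra of real
founder collections, alignment artefacts, and reference-assembly gaps.
Passing tests demonstrate the statistical machinery is correct under
the stated models, not that any particular laboratory population meets
those models.

## Degenerate inputs and tie-breaks

* `ne_from_ft`: `F_t ≤ 0` returns +inf with a warning (no drift
  signal); `F_t ≥ 1` returns the lower bound 0.5 with a warning.
* Rejection sampling with zero acceptances raises an explicit error
  naming the remedies (larger ε, more iterations, rate tuning).
* KDE mode with fewer than two distinct accepted values returns the
  accepted value itself with no bandwidth.
* Window π over zero qualifying positions is undefined and flagged,
  never 0/0.
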