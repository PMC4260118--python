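# haplodrift

Drift simulation, temporal effective-population-size estimation and
diversity summaries for outbred laboratory populations of haplodiploid
insects (parasitoid wasps and other Hymenoptera).

Maintaining an outbred laboratory stock means fighting genetic drift
with husbandry: how many mated females to transfer, in how many
replicate tubes, with how much mixing. This package answers the three
questions that workflow raises:

1. **How much drift should the scheme produce?** A forward Monte-Carlo
   simulator follows a biallelic locus through a tube-propagation
   schedule (diploid females, haploid males, configurable sex ratio and
   mixing) and converts the mean temporal differentiation
   `F_t` into an effective size by inverting the drift expectation
   `E[F_t] = 1 − (1 − 1/(2Nₑ))^t`. The classical haplodiploid
   prediction `Nₑ = 9N_f N_m / (2N_f + 4N_m)` is the built-in closed-form
   reference.
2. **How much drift did the population actually record?** An ABC
   rejection estimator (`TemporalNeABC.fit()`) compares a multilocus
   panel genotyped at several generations against a diploid
   Wright–Fisher forward model via nine summary statistics (mean
   alleles/locus, mean expected heterozygosity, and `F_t` at each of
   three generations), returning the posterior of realized Nₑ.
3. **How diverse is the stock?** Classical microsatellite statistics
   (unbiased H_E, rarefied allelic richness, Weir–Cockerham F_ST with
   permutation tests) and pool-seq summaries (SNP filtering by quality/
   coverage/minor-count rules, 100-kb window SNP density, depth-adjusted
   density and nucleotide diversity π with a coverage-fraction rule).

Synthetic-data generators for all three inputs (founder panels, drift
time series with known Nₑ, pool-seq site tables along five chromosomes)
make every stage runnable and testable without any external data.

## Worked example

Simulate the standard four-tube wasp culture preset (here the
single-tube variant: 120 mated females, male:female ratio 0.89, 32
generations) and estimate Nₑ from the mean drift it produces:

```python
import haplodrift as hd

cfg = hd.hvrx_config(single_tube=True, replicates=20_000, seed=7)
print(hd.run_breeding_scheme(cfg).summary())
```

```
Breeding-scheme drift simulation
  tubes x females/tube : 1 x 120 (males/tube 107, r=0.89)
  founding p0          : 0.5
  generations          : 32
  replicates           : 20000
  mean F_t (final)     : 0.08953
  Ne estimate          : 170.8
```

A mean `F_t` of 0.0895 after 32 generations corresponds to Nₑ ≈ 171,
within a few percent of the closed-form prediction
`wright_ne(120, 107) = 173`: the tube scheme drifts like an ideal
haplodiploid population of that size, i.e. roughly 1.4× its female
census — the point of the breeding design.

Now the inverse problem: generate a 40-locus panel, let it drift at a
*known* Nₑ = 200, genotype 24 females at generations 5, 10 and 32, and
ask the ABC estimator to recover the truth:

```python
base, founder = hd.make_founder_population(hd.FounderSpec(seed=7))
series = hd.drift_series(base, 200, [(5, 24), (10, 24), (32, 24)], seed=8)
model = hd.TemporalNeABC.from_samples(base, series)
fit = model.fit(iterations=100_000, target_rate=0.005, seed=9)
print(fit.summary())
```

```
Temporal Ne estimate (ABC rejection)
  iterations        : 100000
  epsilon (relative) : 0.07065  [tuned]
  accepted          : 500  (rate 0.005)
  posterior mean    : 208.6
  posterior mode    : 200.0
  95% credible int. : [159.0, 274.0]
```

The tolerance was tuned to accept 500 of 10⁵ proposals; the posterior
mode lands on the true value and the 95% credible interval spans about
±30%, the resolution a 40-locus panel genotyped three times can
deliver. `fit.plot_posterior()` draws the density with mean/mode
markers, and `fit.accepted` exposes the raw draws.

The same objects are scriptable from a shell — `haplodrift breed-sim`,
`abc-ne`, `stats`, `fst`, `windows`, and `gen-microsat` / `gen-drift` /
`gen-poolseq` for the generators; see `haplodrift --help`.

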