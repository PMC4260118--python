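"""Synthetic inputs for every analysis stage.

Three generators, all seed-deterministic:

* :func:`make_founder_population` — a multiallelic microsatellite panel
  (default 40 loci, 2-6 alleles each) whose mean gene diversity is
  rejection-sampled into a target band, emulating a moderately diverse
  outbred founder stock, plus a genotyped founder sample.
* :func:`drift_series` — temporal genotype samples from a diploid
  Wright-Fisher population of known Ne, the ground truth for testing
  the ABC estimator end to end.
* :func:`make_poolseq_sites` — per-site pool-seq records along five
  chromosomes with SNP density enriched towards the chromosome tips and
  an over-dispersed read-depth profile that dips near the chromosome
  centres (mimicking low-recombination/low-coverage pericentromeric
  regions), together with the matching per-base depth track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, GenotypeDataset, LocusFrequencies
from .poolseq import SITE_COLUMNS

__all__ = [
    "FounderSpec",
    "PoolSeqSpec",
    "make_founder_population",
    "drift_series",
    "make_poolseq_sites",
]


@dataclass(frozen=True)
class FounderSpec:
    """Founder microsatellite panel specification."""

    n_loci: int = 40
    allele_range: tuple[int, int] = (2, 6)
    concentration: float = 1.0
    he_band: tuple[float, float] = (0.45, 0.65)
    n_individuals: int = 24
    max_retries: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        lo, hi = self.allele_range
        if lo < 2 or hi < lo:
            raise ValueError("allele range must satisfy 2 <= lo <= hi")
        if not 0.0 <= self.he_band[0] < self.he_band[1] <= 1.0:
            raise ValueError("H_E band must be an interval inside [0, 1]")
        if self.n_individuals < 1 or self.concentration <= 0:
            raise ValueError("invalid n_individuals or concentration")


def _labels(k: int) -> np.ndarray:
    # plausible fragment lengths: even sizes from 100 up
    return 100 + 2 * np.arange(k)


def make_founder_population(
    spec: FounderSpec,
) -> tuple[AlleleFrequencyTable, GenotypeDataset]:
    """Draw founder frequencies (rejection-sampled into the H_E band) and
    a genotyped founder sample.

    The returned frequency table is theoretical (``m=None``): it is the
    pool the founder genotypes are drawn from, not an estimate.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.allele_range
    achieved: list[float] = []
    for _ in range(spec.max_retries):
        ks = rng.integers(lo, hi + 1, size=spec.n_loci)
        ps = [rng.dirichlet(np.full(k, spec.concentration)) for k in ks]
        mean_he = float(np.mean([1.0 - np.sum(p**2) for p in ps]))
        achieved.append(mean_he)
        if spec.he_band[0] <= mean_he <= spec.he_band[1]:
            break
    else:
        raise RuntimeError(
            f"could not reach mean H_E in {spec.he_band} after {spec.max_retries} "
            f"draws (achieved range {min(achieved):.3f}-{max(achieved):.3f}); "
            "widen the band or change the concentration"
        )
    table = AlleleFrequencyTable(
        loci={
            f"L{j + 1:03d}": LocusFrequencies(_labels(len(p)), p, None)
            for j, p in enumerate(ps)
        }
    )
    dataset = _sample_genotypes(table, spec.n_individuals, "founder", rng)
    return table, dataset


def _sample_genotypes(
    table: AlleleFrequencyTable,
    n: int,
    population: str,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Draw n diploid individuals from a frequency table (2n gene copies
    multinomially per locus, paired at random)."""
    loci = table.locus_names
    calls_by_locus = []
    for name in loci:
        lf = table[name]
        counts = rng.multinomial(2 * n, lf.p)
        copies = np.repeat(lf.labels, counts)
        rng.shuffle(copies)
        calls_by_locus.append([tuple(sorted(copies[2 * i : 2 * i + 2])) for i in range(n)])
    return GenotypeDataset(
        samples=[(f"{population}_f{i + 1:03d}", population) for i in range(n)],
        loci=loci,
        calls=[[calls_by_locus[j][i] for j in range(len(loci))] for i in range(n)],
    )


def drift_series(
    base: AlleleFrequencyTable,
    ne: int,
    sample_plan: Sequence[tuple[int, int]] = ((5, 24), (10, 24), (32, 24)),
    seed: int | None = None,
    horizon: int | None = None,
) -> dict[int, GenotypeDataset]:
    """Temporal genotype samples under pure diploid Wright-Fisher drift.

    Evolves each locus's base frequencies by multinomial resampling of
    ``2*ne`` gene copies per generation and, at each planned generation
    ``t``, draws the planned number of diploid individuals into a
    dataset whose population id is ``"gen{t}"``.
    """
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    gens = [g for g, _ in sample_plan]
    if gens != sorted(set(gens)) or gens[0] < 1:
        raise ValueError("sample plan generations must be strictly increasing and >= 1")
    horizon = horizon if horizon is not None else gens[-1]
    if gens[-1] > horizon:
        raise ValueError(f"sample plan extends beyond the simulated horizon {horizon}")
    rng = np.random.default_rng(seed)
    freqs = {name: base[name].p.copy() for name in base.locus_names}
    out: dict[int, GenotypeDataset] = {}
    plan = dict(sample_plan)
    for t in range(1, gens[-1] + 1):
        for name in freqs:
            freqs[name] = rng.multinomial(2 * ne, freqs[name]) / (2 * ne)
        if t in plan:
            table = AlleleFrequencyTable(
                loci={
                    name: LocusFrequencies(base[name].labels, freqs[name], None)
                    for name in base.locus_names
                }
            )
            out[t] = _sample_genotypes(table, plan[t], f"gen{t}", rng)
    return out


# ---------------------------------------------------------------------------
# pool-seq


@dataclass(frozen=True)
class PoolSeqSpec:
    """Synthetic pool-seq landscape specification.

    ``snp_density`` is the genome-average SNP rate per bp (default
    2e-3, i.e. about 200 SNPs per 100-kb window); ``tip_enrichment`` is
    the ratio of the position-dependent SNP intensity at a chromosome
    tip relative to its centre (1.0 = uniform).  Read depth follows a
    negative-binomial profile whose mean dips to
    ``center_depth_factor * depth_mean`` at the chromosome centre.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "1": 700_000,
            "2": 650_000,
            "3": 600_000,
            "4": 550_000,
            "5": 500_000,
        }
    )
    snp_density: float = 2.0e-3
    tip_enrichment: float = 3.0
    depth_mean: float = 45.0
    depth_dispersion: float = 8.0
    center_depth_factor: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    cons_qual: tuple[float, float] = (38.0, 8.0)
    map_qual: tuple[float, float] = (50.0, 12.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        if min(self.chrom_lengths.values()) < 1:
            raise ValueError("chromosome lengths must be positive")
        if self.snp_density < 0 or self.tip_enrichment < 0:
            raise ValueError("densities must be non-negative")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("minor-allele frequency range must lie in (0, 0.5]")


_BIN = 1_000  # bp resolution of the position-intensity discretisation
_DEPTH_BLOCK = 100  # bp resolution of the smooth depth profile


def _tip_weight(centers: np.ndarray, length: int, enrichment: float) -> np.ndarray:
    """Relative intensity along the chromosome, mean-normalised to 1."""
    u = np.abs(centers - length / 2.0) / (length / 2.0)
    w = 1.0 + (enrichment - 1.0) * u**2
    return w / w.mean()


def make_poolseq_sites(
    spec: PoolSeqSpec,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, np.ndarray]]:
    """Generate site records, chromosome lengths and the depth track.

    Returns ``(sites, chrom_lengths, depth_track)`` where ``sites`` is a
    DataFrame in the pool-seq site-table layout (sorted, unique
    positions) and ``depth_track[chrom][i]`` is the read depth at
    1-based position ``i+1``.  Candidate SNP positions falling where the
    depth track is below 2 reads are dropped (no variant is observable
    there), so realised density shrinks where coverage collapses.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = dict(spec.chrom_lengths)
    depth_track: dict[str, np.ndarray] = {}
    rows: list[tuple] = []
    bases = np.array(list("ACGT"))
    for chrom, length in chrom_lengths.items():
        # smooth depth profile with a pericentromeric dip + NB noise
        pos0 = np.arange(length)
        block_centers = (pos0 // _DEPTH_BLOCK) * _DEPTH_BLOCK + _DEPTH_BLOCK / 2.0
        u = np.abs(block_centers - length / 2.0) / (length / 2.0)
        c = spec.center_depth_factor
        mu = spec.depth_mean * (c + 3.0 * (1.0 - c) * u**2)  # mean over u in [0,1] ~ depth_mean
        k = spec.depth_dispersion
        track = rng.negative_binomial(k, k / (k + mu)).astype(np.int32)
        depth_track[chrom] = track

        # SNP positions from the tip-enriched intensity
        starts = np.arange(0, length, _BIN)
        ends = np.minimum(starts + _BIN, length)
        bin_len = ends - starts
        centers = (starts + ends) / 2.0
        lam = spec.snp_density * bin_len * _tip_weight(centers, length, spec.tip_enrichment)
        counts = rng.poisson(lam)
        pos_list = [
            rng.integers(starts[i], ends[i], size=n)
            for i, n in enumerate(counts)
            if n > 0
        ]
        pos = np.unique(np.concatenate(pos_list)) if pos_list else np.array([], dtype=int)
        depth = track[pos]
        ok = depth >= 2
        pos, depth = pos[ok], depth[ok]

        maf = rng.uniform(*spec.maf_range, size=pos.size)
        minor = rng.binomial(depth, maf)
        np.minimum(minor, depth - minor, out=minor)  # keep the minor allele minor
        cq = np.clip(rng.normal(*spec.cons_qual, size=pos.size), 2, 60).round(0)
        mq = np.clip(rng.normal(*spec.map_qual, size=pos.size), 0, 60).round(0)
        ref = bases[rng.integers(0, 4, size=pos.size)]
        for i in range(pos.size):
            rows.append(
                (
                    chrom,
                    int(pos[i]) + 1,
                    str(ref[i]),
                    int(depth[i]),
                    (int(depth[i] - minor[i]), int(minor[i])),
                    float(cq[i]),
                    float(mq[i]),
                )
            )
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return sites, chrom_lengths, depth_track
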