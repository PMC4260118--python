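"""ABC rejection estimation of realized Ne from temporal genotype samples.

The estimator treats the trajectory of a multilocus panel re-genotyped
at several generations as the data.  Summary statistics at each
observation generation j are (i) the mean number of alleles per locus,
(ii) the mean unbiased expected heterozygosity, and (iii) the temporal
differentiation F_t against the base population, giving an observed
vector O of length 3 x |generations| (nine elements for the default
generations 5, 10 and 32).

The forward model is a diploid Wright-Fisher population: a proposal Ne
is drawn uniformly from the prior, each locus's base frequency vector is
resampled multinomially as 2*Ne gene copies per generation, and at each
observation generation a sample of the stated number of diploid
individuals is drawn and summarised identically, giving S.  A proposal
is accepted when every element satisfies |S_ij - O_ij| / O_ij < epsilon
(an absolute-distance switch exists for zero-valued observations).  The
posterior is the set of accepted draws; its mode is located by Gaussian
kernel density estimation (Silverman bandwidth) on a unit grid over the
prior range.

``TemporalNeABC`` is the model object (build from summaries or directly
from genotype datasets with :meth:`TemporalNeABC.from_samples`); its
:meth:`~TemporalNeABC.fit` returns a :class:`TemporalNeResults` carrying
the accepted draws, posterior summaries and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .diversity import expected_heterozygosity, temporal_f
from .genotypes import AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "ABCConfig",
    "AcceptanceFailure",
    "summarize_sample",
    "observed_summaries",
    "abc_rejection",
    "TemporalNeABC",
    "TemporalNeResults",
]


class AcceptanceFailure(RuntimeError):
    """Raised when the rejection sampler accepts no draws."""


@dataclass(frozen=True)
class ABCConfig:
    """Rejection-sampler settings.

    ``epsilon`` is a relative tolerance (default 0.11); setting
    ``target_rate`` instead tunes epsilon to the distance quantile that
    accepts that fraction of iterations.  ``batch_size`` only controls
    vectorisation granularity but is part of the random stream, so it
    participates in seed-for-seed reproducibility.
    """

    ne_min: float = 0.0
    ne_max: float = 1000.0
    iterations: int = 100_000
    epsilon: float = 0.11
    target_rate: float | None = None
    generations: tuple[int, ...] = (5, 10, 32)
    sample_sizes: tuple[int, ...] = (24, 24, 24)
    distance: str = "relative"
    seed: int | None = None
    batch_size: int = 10_000

    def __post_init__(self) -> None:
        if self.epsilon <= 0 and self.target_rate is None:
            raise ValueError("epsilon must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.ne_max <= self.ne_min:
            raise ValueError("empty prior range")
        if len(self.generations) != len(self.sample_sizes):
            raise ValueError("generations and sample_sizes differ in length")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2 diploid individuals")
        if list(self.generations) != sorted(set(self.generations)) or self.generations[0] < 1:
            raise ValueError("generations must be strictly increasing and >= 1")
        if self.distance not in ("relative", "absolute"):
            raise ValueError("distance must be 'relative' or 'absolute'")
        if self.target_rate is not None and not 0 < self.target_rate <= 1:
            raise ValueError("target_rate must lie in (0, 1]")


# ---------------------------------------------------------------------------
# summaries


def summarize_sample(
    sample: GenotypeDataset,
    base: AlleleFrequencyTable,
    population: str | None = None,
) -> np.ndarray:
    """Summary triple (mean alleles/locus, mean H_E, F_t vs base) for one sample."""
    if population is None:
        pops = sample.populations
        if len(pops) != 1:
            raise ValueError("dataset holds several populations; name one")
        population = pops[0]
    freqs = allele_frequencies(sample, population)
    missing = [loc for loc in freqs if loc not in base]
    if missing:
        raise ValueError(f"sample loci absent from base table: {missing[:3]}")
    n_alleles = [len(lf.labels) for lf in freqs.loci.values()]
    he = [expected_heterozygosity(lf.p, lf.m) for lf in freqs.loci.values()]
    if not n_alleles:
        raise ValueError("empty sample: no genotyped loci")
    return np.array([np.mean(n_alleles), np.mean(he), temporal_f(base, freqs)])


def observed_summaries(
    samples: Mapping[int, GenotypeDataset],
    base: AlleleFrequencyTable,
) -> np.ndarray:
    """Stack per-generation summary triples into the observed matrix (G, 3)."""
    gens = sorted(samples)
    return np.vstack([summarize_sample(samples[g], base) for g in gens])


# ---------------------------------------------------------------------------
# forward model


def _group_loci(base: AlleleFrequencyTable) -> list[np.ndarray]:
    """Group base frequency vectors by allele count into (L, K) arrays."""
    by_k: dict[int, list[np.ndarray]] = {}
    for lf in base.loci.values():
        by_k.setdefault(len(lf.p), []).append(lf.p)
    return [np.vstack(v) for _, v in sorted(by_k.items())]


def _forward_summaries(
    groups: Sequence[np.ndarray],
    two_ne: np.ndarray,
    generations: Sequence[int],
    sample_sizes: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated summary matrices (B, G, 3) for a batch of proposals."""
    B = two_ne.size
    G = len(generations)
    total_loci = sum(x.shape[0] for x in groups)
    n_all = np.zeros((B, G))
    he = np.zeros((B, G))
    ft_num = np.zeros((B, G))
    ft_cnt = np.zeros((B, G))
    n = two_ne[:, None]
    for x in groups:
        f = np.broadcast_to(x, (B, *x.shape)).copy()
        gen = 0
        for gi, tgen in enumerate(generations):
            while gen < tgen:
                f = rng.multinomial(n, f) / n[..., None]
                gen += 1
            m = 2 * sample_sizes[gi]
            y = rng.multinomial(m, f) / m
            n_all[:, gi] += (y > 0).sum(axis=(1, 2))
            he[:, gi] += (m / (m - 1) * (1.0 - (y**2).sum(-1))).sum(-1)
            denom = (x + y) / 2.0 - x * y
            valid = denom > 0
            fk = np.where(valid, (x - y) ** 2 / np.where(valid, denom, 1.0), 0.0)
            ft_num[:, gi] += fk.sum(axis=(1, 2))
            ft_cnt[:, gi] += valid.sum(axis=(1, 2))
    return np.stack(
        [n_all / total_loci, he / total_loci, ft_num / np.maximum(ft_cnt, 1)], axis=-1
    )


# ---------------------------------------------------------------------------
# rejection sampler


def abc_rejection(
    observed: np.ndarray,
    base: AlleleFrequencyTable,
    config: ABCConfig | None = None,
    **overrides,
) -> "TemporalNeResults":
    """Run the rejection sampler against an observed summary matrix.

    ``observed`` has shape (G, 3) — rows are observation generations,
    columns (mean alleles, mean H_E, F_t) — or is the flat length-3G
    vector in that order.
    """
    cfg = replace(config or ABCConfig(), **overrides) if (config or overrides) else ABCConfig()
    obs = np.asarray(observed, dtype=float).reshape(len(cfg.generations), 3)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed summaries must be finite")
    if cfg.distance == "relative" and np.any(obs == 0):
        raise ValueError(
            "an observed summary element equals 0: relative distance is undefined; "
            "use distance='absolute'"
        )
    rng = np.random.default_rng(cfg.seed)
    groups = _group_loci(base)

    proposals = np.empty(cfg.iterations)
    distances = np.empty(cfg.iterations)
    done = 0
    while done < cfg.iterations:
        b = min(cfg.batch_size, cfg.iterations - done)
        ne = np.maximum(2, np.rint(rng.uniform(cfg.ne_min, cfg.ne_max, size=b))).astype(
            np.int64
        )
        sim = _forward_summaries(groups, 2 * ne, cfg.generations, cfg.sample_sizes, rng)
        if cfg.distance == "relative":
            d = np.abs(sim - obs[None]) / np.abs(obs[None])
        else:
            d = np.abs(sim - obs[None])
        proposals[done : done + b] = ne
        distances[done : done + b] = d.reshape(b, -1).max(axis=1)
        done += b

    if cfg.target_rate is not None:
        epsilon = float(np.quantile(distances, cfg.target_rate))
        mask = distances <= epsilon
    else:
        epsilon = cfg.epsilon
        mask = distances < epsilon
    accepted = proposals[mask]
    if accepted.size == 0:
        raise AcceptanceFailure(
            "no accepted draws: increase epsilon, raise the iteration count, "
            "or use target_rate tuning"
        )
    return TemporalNeResults._from_run(obs, cfg, accepted, epsilon)


# ---------------------------------------------------------------------------
# model / results


class TemporalNeABC:
    """Temporal-sample Ne model: observed summaries plus the base population.

    Parameters
    ----------
    observed : array (G, 3)
        Observed summary matrix (mean alleles, mean H_E, F_t per generation).
    base : AlleleFrequencyTable
        Base-population allele frequencies the forward model starts from.
    generations, sample_sizes :
        Observation design; defaults 5/10/32 with 24 diploid females each.
    """

    def __init__(
        self,
        observed: np.ndarray,
        base: AlleleFrequencyTable,
        generations: tuple[int, ...] = (5, 10, 32),
        sample_sizes: tuple[int, ...] = (24, 24, 24),
        ne_min: float = 0.0,
        ne_max: float = 1000.0,
    ) -> None:
        self.base = base
        self.generations = tuple(generations)
        self.sample_sizes = tuple(sample_sizes)
        self.ne_min = ne_min
        self.ne_max = ne_max
        self.observed = np.asarray(observed, dtype=float).reshape(len(self.generations), 3)

    @classmethod
    def from_samples(
        cls,
        base: AlleleFrequencyTable,
        samples: Mapping[int, GenotypeDataset],
        **kwargs,
    ) -> "TemporalNeABC":
        """Build the model by summarising genotype datasets keyed by generation."""
        gens = tuple(sorted(samples))
        obs = observed_summaries(samples, base)
        sizes = tuple(samples[g].n_samples for g in gens)
        kwargs.setdefault("generations", gens)
        kwargs.setdefault("sample_sizes", sizes)
        return cls(obs, base, **kwargs)

    def fit(
        self,
        iterations: int = 100_000,
        epsilon: float = 0.11,
        target_rate: float | None = None,
        distance: str = "relative",
        seed: int | None = None,
        batch_size: int = 10_000,
    ) -> "TemporalNeResults":
        cfg = ABCConfig(
            ne_min=self.ne_min,
            ne_max=self.ne_max,
            iterations=iterations,
            epsilon=epsilon,
            target_rate=target_rate,
            generations=self.generations,
            sample_sizes=self.sample_sizes,
            distance=distance,
            seed=seed,
            batch_size=batch_size,
        )
        return abc_rejection(self.observed, self.base, cfg)


@dataclass(frozen=True)
class TemporalNeResults:
    """Accepted draws and posterior summaries from one rejection run."""

    observed: np.ndarray = field(repr=False)
    config: ABCConfig = field(repr=False)
    accepted: np.ndarray = field(repr=False)
    epsilon: float
    acceptance_rate: float
    posterior_mean: float
    posterior_mode: float
    kde_bandwidth: float | None

    @classmethod
    def _from_run(
        cls, observed: np.ndarray, cfg: ABCConfig, accepted: np.ndarray, epsilon: float
    ) -> "TemporalNeResults":
        mode, bw = _kde_mode(accepted, cfg.ne_min, cfg.ne_max)
        return cls(
            observed=observed,
            config=cfg,
            accepted=accepted,
            epsilon=epsilon,
            acceptance_rate=accepted.size / cfg.iterations,
            posterior_mean=float(accepted.mean()),
            posterior_mode=mode,
            kde_bandwidth=bw,
        )

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.size)

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(self.accepted, [lo, 1.0 - lo]))

    def posterior_density(self, grid: np.ndarray | None = None):
        """(grid, density) from the Gaussian KDE over the prior range."""
        from scipy.stats import gaussian_kde

        if grid is None:
            grid = np.arange(self.config.ne_min, self.config.ne_max + 1.0)
        kde = gaussian_kde(self.accepted, bw_method="silverman")
        return grid, kde(grid)

    def plot_posterior(self, ax=None):
        """Plot the posterior density with mean/mode markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid, dens = self.posterior_density()
        ax.plot(grid, dens, lw=1.5)
        ax.axvline(self.posterior_mean, color="red", ls="--", label="posterior mean")
        ax.axvline(self.posterior_mode, color="green", ls=":", label="posterior mode")
        ax.set_xlabel("Ne (diploid individuals)")
        ax.set_ylabel("posterior density")
        ax.legend()
        return ax

    def summary(self) -> str:
        ci = self.credible_interval()
        lines = [
            "Temporal Ne estimate (ABC rejection)",
            f"  iterations        : {self.config.iterations}",
            f"  epsilon ({self.config.distance:>8}) : {self.epsilon:.4g}"
            + ("  [tuned]" if self.config.target_rate is not None else ""),
            f"  accepted          : {self.n_accepted}"
            f"  (rate {self.acceptance_rate:.4g})",
            f"  posterior mean    : {self.posterior_mean:.1f}",
            f"  posterior mode    : {self.posterior_mode:.1f}",
            f"  95% credible int. : [{ci[0]:.1f}, {ci[1]:.1f}]",
        ]
        return "\n".join(lines)


def _kde_mode(accepted: np.ndarray, lo: float, hi: float) -> tuple[float, float | None]:
    """Posterior mode via Gaussian KDE (Silverman) on a unit grid."""
    if accepted.size < 2 or np.ptp(accepted) == 0:
        return float(accepted[0]), None
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(accepted, bw_method="silverman")
    grid = np.arange(lo, hi + 1.0)
    dens = kde(grid)
    return float(grid[np.argmax(dens)]), float(kde.factor * accepted.std(ddof=1))
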