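"""Forward Monte-Carlo drift simulation of a haplodiploid breeding scheme.

Models a single biallelic locus in a laboratory population propagated in
``n_tubes`` parallel culture tubes.  Females are diploid, males haploid
(developing from unfertilized eggs, so they carry a single maternal
allele).  Each generation, per tube, the ``N_f`` resident females
produce a pool of ``round(r * N_f)`` haploid sons (each from a random
mother, inheriting one of her two alleles) and ``N_f`` diploid
daughters, each receiving one random allele of a random mother plus the
allele of a father selected with replacement from the tube's male pool.
When several tubes are run, the offspring are pooled across tubes and
redistributed in equal numbers to fresh tubes before they reproduce,
which is what keeps parallel tubes from diverging into separate
populations.

By default each daughter's father is an independent draw from the male
pool, the random-union mating the classical closed-form effective-size
prediction assumes.  Setting ``monogamous=True`` instead mates every
female to a single male so that all her daughters share one father;
this brood structure roughly halves the effective number of males and
is provided for comparing maintenance regimes, not as the default
model.

Drift is quantified per generation by the temporal differentiation F_t
of the census female allele frequency against the founding frequency
``p0`` (Nei-Tajima F_c), averaged over replicates, and converted to an
effective population size by inverting the pure-drift expectation

    E[F_t] = 1 - (1 - 1/(2 Ne))^t.

``wright_ne`` gives the classical closed-form inbreeding effective size
of a haplodiploid population with ``N_f`` females and ``N_m`` males for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreedingConfig",
    "SimResult",
    "run_breeding_scheme",
    "ne_from_ft",
    "wright_ne",
    "hvrx_config",
]


@dataclass(frozen=True)
class BreedingConfig:
    """Parameters of the tube-propagation drift simulator.

    Parameters
    ----------
    n_tubes : int
        Parallel culture tubes (1 = single large population).
    females_per_tube : int
        Mated females transferred per tube each generation (N_f per tube).
    male_ratio : float
        Males per female, r; the per-tube male pool has ``round(r * N_f)``
        members (at least 1).
    p0 : float
        Founding frequency of the tracked allele, in (0, 1).
    generations : int
        Number of propagation cycles simulated.
    replicates : int
        Independent Monte-Carlo replicates averaged for mean F_t.
    seed : int or None
        Seed for the random generator; identical seed + config gives a
        bit-identical result.
    include_males_in_census : bool
        If True the census frequency also counts the single gene copy of
        each male; default counts female copies only, matching panels
        that genotype females.
    monogamous : bool
        If True, each female mates with one male and all her daughters
        share that father; default False (each daughter's father is an
        independent draw from the male pool).
    """

    n_tubes: int = 4
    females_per_tube: int = 30
    male_ratio: float = 1.0
    p0: float = 0.5
    generations: int = 32
    replicates: int = 10_000
    seed: int | None = None
    include_males_in_census: bool = False
    monogamous: bool = False
    keep_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.n_tubes < 1 or self.females_per_tube < 1:
            raise ValueError("n_tubes and females_per_tube must be >= 1")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly inside (0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.males_per_tube < 1:
            raise ValueError("male_ratio too small: no males in the per-tube pool")

    @property
    def males_per_tube(self) -> int:
        return max(1, round(self.male_ratio * self.females_per_tube))

    @property
    def total_females(self) -> int:
        return self.n_tubes * self.females_per_tube


@dataclass(frozen=True)
class SimResult:
    """Mean F_t trajectory and the Ne estimate derived from it.

    ``final_frequencies`` holds the census allele frequency of every
    replicate at the last generation; ``frequency_trajectories`` the
    full (replicates, generations) frequency paths when the config asked
    for them.
    """

    mean_ft: np.ndarray
    ne_estimate: float
    replicates: int
    final_frequencies: np.ndarray = field(repr=False)
    config: BreedingConfig = field(repr=False)
    frequency_trajectories: np.ndarray | None = field(default=None, repr=False)

    @property
    def final_mean_ft(self) -> float:
        return float(self.mean_ft[-1])

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Breeding-scheme drift simulation",
            f"  tubes x females/tube : {cfg.n_tubes} x {cfg.females_per_tube}"
            f" (males/tube {cfg.males_per_tube}, r={cfg.male_ratio:g})",
            f"  founding p0          : {cfg.p0:g}",
            f"  generations          : {cfg.generations}",
            f"  replicates           : {self.replicates}",
            f"  mean F_t (final)     : {self.final_mean_ft:.5f}",
            f"  Ne estimate          : {self.ne_estimate:.1f}",
        ]
        return "\n".join(lines)


def hvrx_config(single_tube: bool = False, **overrides) -> BreedingConfig:
    """Preset mirroring the HVRx wasp culture: 4 x 30 (or 1 x 120) mated
    females per generation, with a male:female ratio of 0.89 chosen so that
    the closed-form prediction for the census equals Ne = 173."""
    base = dict(
        n_tubes=1 if single_tube else 4,
        females_per_tube=120 if single_tube else 30,
        male_ratio=0.89,
        p0=0.5,
        generations=32,
    )
    base.update(overrides)
    return BreedingConfig(**base)


# ---------------------------------------------------------------------------


def _balanced_alleles(rng: np.random.Generator, shape: tuple[int, ...], p: float) -> np.ndarray:
    """0/1 array whose per-replicate mean is as close to p as rounding allows."""
    reps = shape[0]
    per_rep = int(np.prod(shape[1:]))
    k = round(p * per_rep)
    flat = np.zeros((reps, per_rep), dtype=np.int8)
    flat[:, :k] = 1
    order = np.argsort(rng.random((reps, per_rep)), axis=1)
    return np.take_along_axis(flat, order, axis=1).reshape(shape)


def _ft_biallelic(p0: float, pt: np.ndarray) -> np.ndarray:
    """Nei-Tajima F_c for a biallelic locus (both alleles give the same value)."""
    denom = (p0 + pt) / 2.0 - p0 * pt
    out = np.zeros_like(pt)
    ok = denom > 0
    out[ok] = (p0 - pt[ok]) ** 2 / denom[ok]
    return out


def run_breeding_scheme(config: BreedingConfig) -> SimResult:
    """Simulate the propagation scheme and estimate Ne from mean F_t.

    Founding mated females are initialised at exactly ``p0`` (balanced
    allele assignment, shuffled within each replicate) so that mean F_t
    measures only the variance the scheme itself generates.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    R, T, N = cfg.replicates, cfg.n_tubes, cfg.females_per_tube
    M = cfg.males_per_tube

    fem_a = _balanced_alleles(rng, (R, T, N), cfg.p0)
    fem_b = _balanced_alleles(rng, (R, T, N), cfg.p0)
    males = _balanced_alleles(rng, (R, T, M), cfg.p0)

    def _maternal(shape: tuple[int, ...]) -> np.ndarray:
        """One random allele of a random resident mother, per slot."""
        mom = rng.integers(0, N, size=shape)
        pick = rng.integers(0, 2, size=shape, dtype=np.int8).astype(bool)
        return np.where(
            pick,
            np.take_along_axis(fem_a, mom, axis=2),
            np.take_along_axis(fem_b, mom, axis=2),
        ), mom

    mean_ft = np.empty(cfg.generations, dtype=float)
    traj = np.empty((R, cfg.generations)) if cfg.keep_trajectories else None
    pt = np.full(R, cfg.p0)
    for gen in range(cfg.generations):
        # haploid sons carry one maternal allele (unfertilized eggs)
        sons, _ = _maternal((R, T, M))
        # diploid daughters: maternal allele + a father from the tube's pool
        dau_a, dau_mom = _maternal((R, T, N))
        if cfg.monogamous:
            mate_alleles = np.take_along_axis(
                males, rng.integers(0, M, size=(R, T, N)), axis=2
            )  # one mate per resident female; broods share him
            dau_b = np.take_along_axis(mate_alleles, dau_mom, axis=2)
        else:
            dau_b = np.take_along_axis(males, rng.integers(0, M, size=(R, T, N)), axis=2)

        if T > 1:  # pool offspring across tubes, redeal in equal numbers
            order = np.argsort(rng.random((R, T * N)), axis=1)
            dau_a = np.take_along_axis(dau_a.reshape(R, T * N), order, axis=1).reshape(R, T, N)
            dau_b = np.take_along_axis(dau_b.reshape(R, T * N), order, axis=1).reshape(R, T, N)
            order_m = np.argsort(rng.random((R, T * M)), axis=1)
            sons = np.take_along_axis(sons.reshape(R, T * M), order_m, axis=1).reshape(R, T, M)

        fem_a, fem_b, males = dau_a, dau_b, sons
        copies = fem_a.sum(axis=(1, 2)) + fem_b.sum(axis=(1, 2))
        total = 2 * T * N
        if cfg.include_males_in_census:
            copies = copies + males.sum(axis=(1, 2))
            total += T * M
        pt = copies / total
        mean_ft[gen] = _ft_biallelic(cfg.p0, pt).mean()
        if traj is not None:
            traj[:, gen] = pt

    ne = ne_from_ft(float(mean_ft[-1]), cfg.generations)
    return SimResult(
        mean_ft=mean_ft,
        ne_estimate=ne,
        replicates=R,
        final_frequencies=pt,
        config=cfg,
        frequency_trajectories=traj,
    )


def ne_from_ft(mean_ft: float, t: int) -> float:
    """Invert E[F_t] = 1 - (1 - 1/(2 Ne))^t for Ne.

    Degenerate inputs are flagged with a warning: ``mean_ft <= 0`` means
    no measurable drift (returns ``inf``), ``mean_ft >= 1`` complete
    fixation faster than the model allows (returns the t-generation
    lower bound Ne = 0.5).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if mean_ft <= 0.0:
        warnings.warn("mean F_t <= 0: no drift signal, Ne unbounded", stacklevel=2)
        return float("inf")
    if mean_ft >= 1.0:
        warnings.warn("mean F_t >= 1: degenerate, returning the Ne lower bound", stacklevel=2)
        return 0.5
    return 1.0 / (2.0 * (1.0 - (1.0 - mean_ft) ** (1.0 / t)))


def wright_ne(n_f: float, n_m: float) -> float:
    """Wright's inbreeding effective size of a haplodiploid population,
    9 N_f N_m / (2 N_f + 4 N_m)."""
    if n_f <= 0 or n_m <= 0:
        raise ValueError("female and male counts must be positive")
    return 9.0 * n_f * n_m / (2.0 * n_f + 4.0 * n_m)
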