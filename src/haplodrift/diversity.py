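"""Microsatellite diversity and differentiation statistics.

Implements the classical panel-survey toolkit for multiallelic
codominant markers:

* unbiased expected heterozygosity (Nei's gene diversity with the
  ``m/(m-1)`` gene-copy correction),
* allelic richness by rarefaction (El Mousadik & Petit estimator),
* multilocus Weir & Cockerham (1984) theta with a genotype-permutation
  significance test,
* the temporal allelic differentiation F_c of Nei & Tajima, used to
  calibrate drift against a founding population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "expected_heterozygosity",
    "allelic_richness",
    "temporal_f",
    "pairwise_fst",
    "PairwiseFst",
    "diversity_table",
]


def expected_heterozygosity(p, m: int) -> float:
    """Unbiased expected heterozygosity m/(m-1) * (1 - sum p_i^2).

    Parameters
    ----------
    p : array-like of float
        Allele frequencies, summing to 1.
    m : int
        Gene copies behind the estimate (2 x genotyped diploids); >= 2.
    """
    p = np.asarray(p, dtype=float)
    if m < 2:
        raise ValueError("gene-copy count m must be >= 2")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("frequencies must be non-negative and sum to 1")
    return float(m / (m - 1) * (1.0 - np.sum(p**2)))


def allelic_richness(allele_copy_counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Rarefaction of observed allele copy counts: sum over alleles of
    ``1 - C(M - M_i, g) / C(M, g)`` with ``M`` the total copy count and
    ``M_i`` the count of allele ``i``.  Exact (integer binomials).
    """
    counts = np.asarray(allele_copy_counts, dtype=int)
    if np.any(counts < 0) or counts.sum() < 1:
        raise ValueError("allele copy counts must be non-negative with a positive sum")
    counts = counts[counts > 0]
    M = int(counts.sum())
    if not 1 <= g <= M:
        raise ValueError(f"rarefaction size g={g} must be in [1, {M}]")
    denom = math.comb(M, g)
    return float(sum(1.0 - math.comb(M - int(Mi), g) / denom for Mi in counts))


def temporal_f(p0: AlleleFrequencyTable, pt: AlleleFrequencyTable) -> float:
    """Temporal allelic differentiation F_c between two frequency tables.

    For each allele k with founding frequency x and current frequency y,

        f_k = (x - y)^2 / ((x + y)/2 - x*y)

    and F_c is the mean of f_k over all alleles of all shared loci.
    Alleles absent from one table contribute with frequency 0; alleles
    identically fixed or identically absent in both tables (x = y in
    {0, 1}, degenerate denominator) are skipped.
    """
    shared = [loc for loc in p0 if loc in pt]
    if not shared:
        raise ValueError("frequency tables share no loci")
    num: list[float] = []
    for loc in shared:
        a, b = p0[loc], pt[loc]
        labels = np.union1d(a.labels, b.labels)
        x = np.array([a.frequency(l) for l in labels])
        y = np.array([b.frequency(l) for l in labels])
        denom = (x + y) / 2.0 - x * y
        keep = denom > 0
        num.extend(((x[keep] - y[keep]) ** 2 / denom[keep]).tolist())
    return float(np.mean(num)) if num else 0.0


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


@dataclass(frozen=True)
class PairwiseFst:
    """Multilocus theta for one population pair with permutation p-value."""

    populations: tuple[str, str]
    theta: float
    p_value: float | None
    n_permutations: int
    defined: bool = True


def _wc_sums(calls_a, calls_b) -> tuple[float, float]:
    """Summed Weir-Cockerham (a, a+b+c) components over loci and alleles.

    ``calls_a`` / ``calls_b`` are per-locus lists of non-missing diploid
    calls (tuples) for the two populations.
    """
    r = 2
    num = 0.0
    den = 0.0
    for rows in zip(calls_a, calls_b):
        ns = [len(rows[0]), len(rows[1])]
        if min(ns) < 1 or sum(ns) < 2:
            continue
        alleles = sorted({a for rows_i in rows for c in rows_i for a in c})
        if len(alleles) < 2:
            continue
        nbar = (ns[0] + ns[1]) / r
        nc = (r * nbar - (ns[0] ** 2 + ns[1] ** 2) / (r * nbar)) / (r - 1)
        if nc <= 0 or nbar <= 1:
            continue
        for allele in alleles:
            ps = []
            hs = []
            for rows_i, n_i in zip(rows, ns):
                copies = sum(c.count(allele) for c in rows_i)
                het = sum(1 for c in rows_i if c[0] != c[1] and allele in c)
                ps.append(copies / (2 * n_i))
                hs.append(het / n_i)
            pbar = (ns[0] * ps[0] + ns[1] * ps[1]) / (r * nbar)
            s2 = (ns[0] * (ps[0] - pbar) ** 2 + ns[1] * (ps[1] - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (ns[0] * hs[0] + ns[1] * hs[1]) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num, den


def _locus_calls(dataset: GenotypeDataset, idx) -> list[list[tuple[int, int]]]:
    return [
        [dataset.calls[i][j] for i in idx if dataset.calls[i][j] is not None]
        for j in range(len(dataset.loci))
    ]


def pairwise_fst(
    dataset: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> PairwiseFst:
    """Multilocus Weir-Cockerham theta between two populations.

    theta is the ratio of the among-population variance component to the
    total, summed over all alleles of all loci.  Significance is assessed
    by randomly reassigning genotyped individuals (whole multilocus
    genotypes) to the two populations ``n_perm`` times and counting
    permuted ``|theta|`` at least as large as observed, with +1 smoothing
    on numerator and denominator.  ``n_perm=0`` skips the test.
    """
    ia = dataset.population_indices(pop_a)
    ib = dataset.population_indices(pop_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both populations need at least two genotyped samples")
    num, den = _wc_sums(_locus_calls(dataset, ia), _locus_calls(dataset, ib))
    if den == 0.0:
        return PairwiseFst((pop_a, pop_b), float("nan"), None, 0, defined=False)
    theta = num / den
    if n_perm <= 0:
        return PairwiseFst((pop_a, pop_b), theta, None, 0)
    rng = np.random.default_rng(seed)
    pool = np.array(ia + ib)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        pa, pb = perm[: len(ia)], perm[len(ia) :]
        pn, pdn = _wc_sums(_locus_calls(dataset, pa), _locus_calls(dataset, pb))
        if pdn != 0 and abs(pn / pdn) >= abs(theta):
            hits += 1
    return PairwiseFst((pop_a, pop_b), theta, (hits + 1) / (n_perm + 1), n_perm)


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean significance mask after Bonferroni correction."""
    p = np.asarray(p_values, dtype=float)
    return p <= alpha / p.size


# ---------------------------------------------------------------------------
# survey tables


def diversity_table(
    dataset: GenotypeDataset,
    populations=None,
    rarefaction_size: int | None = None,
) -> pd.DataFrame:
    """Per-population mean +/- SE of H_E and rarefied allelic richness.

    Richness is rarefied to the smallest per-locus gene-copy count over
    all compared populations (the convention for panels with unequal
    sample sizes), unless ``rarefaction_size`` is given.
    """
    populations = list(populations) if populations is not None else dataset.populations
    tables = {pop: allele_frequencies(dataset, pop) for pop in populations}
    if rarefaction_size is None:
        ms = [lf.m for tab in tables.values() for lf in tab.loci.values()]
        rarefaction_size = min(ms)
    rows = []
    for pop, tab in tables.items():
        he = [expected_heterozygosity(lf.p, lf.m) for lf in tab.loci.values()]
        rich = [
            allelic_richness(np.rint(lf.p * lf.m).astype(int), min(rarefaction_size, lf.m))
            for lf in tab.loci.values()
        ]
        rows.append(
            {
                "population": pop,
                "n_loci": len(tab),
                "mean_He": np.mean(he),
                "se_He": np.std(he, ddof=1) / math.sqrt(len(he)) if len(he) > 1 else np.nan,
                "mean_richness": np.mean(rich),
                "se_richness": np.std(rich, ddof=1) / math.sqrt(len(rich))
                if len(rich) > 1
                else np.nan,
                "rarefaction_size": rarefaction_size,
            }
        )
    return pd.DataFrame(rows)
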