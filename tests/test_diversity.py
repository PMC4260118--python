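"""Diversity statistics against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import haplodrift as hd
from tests.conftest import make_two_pop_table


class TestExpectedHeterozygosity:
    def test_hand_values(self):
        assert hd.expected_heterozygosity([1.0], 10) == 0.0
        assert hd.expected_heterozygosity([0.5, 0.5], 20) == pytest.approx(
            20 / 19 * 0.5, abs=1e-12
        )

    def test_equifrequent_large_sample_limit(self):
        he = hd.expected_heterozygosity([0.25] * 4, 10**9)
        assert he == pytest.approx(0.75, rel=1e-6)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            hd.expected_heterozygosity([0.5, 0.5], 1)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6), st.integers(2, 60))
    def test_permutation_invariant_and_bounded(self, weights, m):
        m = max(m, len(weights))  # a sample of m copies can show at most m alleles
        p = np.array(weights) / np.sum(weights)
        he = hd.expected_heterozygosity(p, m)
        assert he == pytest.approx(
            hd.expected_heterozygosity(np.roll(p, 1), m), abs=1e-12
        )
        assert -1e-12 <= he <= 1.0 + 1e-9  # cap 1: all m copies distinct

    def test_decreasing_in_dominant_frequency(self):
        values = [
            hd.expected_heterozygosity([q, 1 - q], 40) for q in (0.5, 0.6, 0.75, 0.9)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


def enumeration_richness(counts, g):
    """Oracle: mean distinct alleles over every g-subset of the gene copies."""
    copies = [a for a, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(copies)), g))
    return float(
        np.mean([len({copies[i] for i in sub}) for sub in subsets])
    )


class TestAllelicRichness:
    def test_hand_values(self):
        assert hd.allelic_richness([10], 10) == pytest.approx(1.0)
        assert hd.allelic_richness([2, 2], 2) == pytest.approx(5 / 3, abs=1e-12)
        assert hd.allelic_richness([1, 1, 1], 3) == pytest.approx(3.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hd.allelic_richness([2, 2], 5)
        with pytest.raises(ValueError):
            hd.allelic_richness([0, 0], 1)

    @settings(max_examples=80, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        counts = data.draw(
            st.lists(st.integers(0, 6), min_size=1, max_size=4).filter(
                lambda c: 1 <= sum(c) <= 10
            )
        )
        g = data.draw(st.integers(1, sum(counts)))
        assert hd.allelic_richness(counts, g) == pytest.approx(
            enumeration_richness(counts, g), abs=1e-9
        )

    def test_monotone_in_rarefaction_size(self):
        counts = [5, 3, 2, 1]
        values = [hd.allelic_richness(counts, g) for g in range(1, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestTemporalF:
    def test_identity_is_zero(self):
        t = hd.table_from_frequencies({"L1": ([1, 2], [0.3, 0.7])})
        assert hd.temporal_f(t, t) == 0.0

    def test_hand_values(self):
        x = hd.table_from_frequencies({"L1": ([1, 2], [0.5, 0.5])})
        fixed = hd.table_from_frequencies({"L1": ([1], [1.0])})
        assert hd.temporal_f(x, fixed) == pytest.approx(1.0, abs=1e-9)
        y = hd.table_from_frequencies({"L1": ([1, 2], [0.6, 0.4])})
        assert hd.temporal_f(x, y) == pytest.approx(0.04, abs=1e-9)

    def test_identically_fixed_alleles_are_skipped(self):
        a = hd.table_from_frequencies({"L1": ([1], [1.0]), "L2": ([1, 2], [0.5, 0.5])})
        b = hd.table_from_frequencies({"L1": ([1], [1.0]), "L2": ([1, 2], [0.4, 0.6])})
        only_l2 = hd.temporal_f(
            hd.table_from_frequencies({"L2": ([1, 2], [0.5, 0.5])}),
            hd.table_from_frequencies({"L2": ([1, 2], [0.4, 0.6])}),
        )
        assert hd.temporal_f(a, b) == pytest.approx(only_l2, abs=1e-12)

    def test_disjoint_loci_rejected(self):
        a = hd.table_from_frequencies({"L1": ([1], [1.0])})
        b = hd.table_from_frequencies({"L2": ([1], [1.0])})
        with pytest.raises(ValueError):
            hd.temporal_f(a, b)

    def test_non_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet([1, 1, 1])
            q = rng.dirichlet([1, 1, 1])
            a = hd.table_from_frequencies({"L": ([1, 2, 3], p)})
            b = hd.table_from_frequencies({"L": ([1, 2, 3], q)})
            assert hd.temporal_f(a, b) >= 0.0


def brute_force_theta(dataset, pop_a, pop_b):
    """Oracle: Weir-Cockerham variance components written out explicitly,
    one allele at a time, with plain Python arithmetic."""
    idx = {p: dataset.population_indices(p) for p in (pop_a, pop_b)}
    num = den = 0.0
    for j in range(len(dataset.loci)):
        geno = {
            p: [dataset.calls[i][j] for i in idx[p] if dataset.calls[i][j] is not None]
            for p in (pop_a, pop_b)
        }
        n1, n2 = len(geno[pop_a]), len(geno[pop_b])
        if n1 == 0 or n2 == 0:
            continue
        alleles = sorted({a for rows in geno.values() for c in rows for a in c})
        if len(alleles) < 2:
            continue
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        for allele in alleles:
            p1 = sum(c.count(allele) for c in geno[pop_a]) / (2 * n1)
            p2 = sum(c.count(allele) for c in geno[pop_b]) / (2 * n2)
            h1 = sum(1 for c in geno[pop_a] if c[0] != c[1] and allele in c) / n1
            h2 = sum(1 for c in geno[pop_b] if c[0] != c[1] and allele in c) / n2
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


FST_TOY = """sample_id\tpopulation_id\tL1
a1\tA\t100/100
a2\tA\t100/102
a3\tA\t100/100
a4\tA\t102/102
b1\tB\t102/102
b2\tB\t100/102
b3\tB\t102/102
b4\tB\t102/102
"""


class TestPairwiseFst:
    def test_matches_brute_force_on_toy_table(self):
        ds = hd.read_genotypes(FST_TOY)
        res = hd.pairwise_fst(ds, "A", "B", n_perm=0)
        assert res.theta == pytest.approx(brute_force_theta(ds, "A", "B"), abs=1e-12)

    def test_matches_brute_force_on_random_multilocus_table(self):
        ds = make_two_pop_table(np.random.default_rng(5), n_per_pop=6, n_loci=4)
        res = hd.pairwise_fst(ds, "x", "y", n_perm=0)
        assert res.theta == pytest.approx(brute_force_theta(ds, "x", "y"), abs=1e-12)

    def test_identical_multisets_near_zero(self):
        """Two copies of the same genotype multiset: theta is a small
        negative number (unbiased estimator, zero among-population
        variance) and the permutation test sees nothing."""
        rows = ["sample_id\tpopulation_id\tL1\tL2"]
        genos = ["100/102\t120/124", "100/100\t120/120", "102/102\t124/124"] * 4
        for pop in ("A", "B"):
            for i, g in enumerate(genos):
                rows.append(f"{pop}{i}\t{pop}\t{g}")
        ds = hd.read_genotypes("\n".join(rows) + "\n")
        res = hd.pairwise_fst(ds, "A", "B", n_perm=199, seed=0)
        assert res.theta <= 0.0 and abs(res.theta) < 0.1
        assert res.p_value > 0.2

    def test_fixed_difference_gives_one(self):
        rows = ["sample_id\tpopulation_id\tL1"]
        rows += [f"a{i}\tA\t100/100" for i in range(4)]
        rows += [f"b{i}\tB\t102/102" for i in range(4)]
        ds = hd.read_genotypes("\n".join(rows) + "\n")
        assert hd.pairwise_fst(ds, "A", "B", n_perm=0).theta == pytest.approx(1.0)

    def test_undefined_without_polymorphism(self):
        rows = ["sample_id\tpopulation_id\tL1"]
        rows += [f"a{i}\tA\t100/100" for i in range(2)]
        rows += [f"b{i}\tB\t100/100" for i in range(2)]
        ds = hd.read_genotypes("\n".join(rows) + "\n")
        res = hd.pairwise_fst(ds, "A", "B", n_perm=0)
        assert not res.defined

    def test_null_permutation_p_roughly_uniform(self):
        """Splitting one homogeneous sample in two: p <= 0.05 in about 5%
        of replicate runs (binomial tolerance around 10/200)."""
        rng = np.random.default_rng(123)
        hits = 0
        for k in range(200):
            ds = make_two_pop_table(rng, n_per_pop=6, n_loci=3)
            res = hd.pairwise_fst(ds, "x", "y", n_perm=99, seed=k)
            hits += res.p_value <= 0.05
        assert 2 <= hits <= 25


def test_diversity_table_shape(founder):
    _, ds = founder
    table = hd.diversity_table(ds)
    assert set(table.columns) >= {"population", "mean_He", "se_He", "mean_richness"}
    row = table.iloc[0]
    assert 0 < row.mean_He < 1
    assert 1 <= row.mean_richness <= 6
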