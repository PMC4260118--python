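"""ABC rejection estimator: summaries, limits, invariances."""

import numpy as np
import pytest

import haplodrift as hd
from haplodrift.temporal_ne import AcceptanceFailure, observed_summaries


def _monomorphic_pair():
    base = hd.table_from_frequencies({"L1": ([100], [1.0])})
    ds = hd.read_genotypes(
        "sample_id\tpopulation_id\tL1\ns1\tgen5\t100/100\ns2\tgen5\t100/100\n"
    )
    return base, ds


class TestSummaries:
    def test_monomorphic_degenerate_triple(self):
        base, ds = _monomorphic_pair()
        triple = hd.summarize_sample(ds, base)
        assert triple.tolist() == [1.0, 0.0, 0.0]

    def test_ft_element_zero_when_sample_matches_base(self):
        base = hd.table_from_frequencies({"L1": ([100, 102], [0.5, 0.5])})
        ds = hd.read_genotypes(
            "sample_id\tpopulation_id\tL1\ns1\tg\t100/102\ns2\tg\t100/102\n"
        )
        triple = hd.summarize_sample(ds, base)
        assert triple[2] == 0.0

    def test_toy_table_matches_composed_hand_computation(self):
        """4 samples x 2 loci: the triple equals the composition of the
        individually tested statistics."""
        text = (
            "sample_id\tpopulation_id\tL1\tL2\n"
            "s1\tg\t100/102\t200/200\n"
            "s2\tg\t100/100\t200/204\n"
            "s3\tg\t102/102\t200/200\n"
            "s4\tg\t100/102\t200/200\n"
        )
        ds = hd.read_genotypes(text)
        base = hd.table_from_frequencies(
            {"L1": ([100, 102], [0.5, 0.5]), "L2": ([200, 204], [0.9, 0.1])}
        )
        triple = hd.summarize_sample(ds, base)
        freqs = hd.allele_frequencies(ds, "g")
        he = np.mean(
            [
                hd.expected_heterozygosity(freqs["L1"].p, 8),
                hd.expected_heterozygosity(freqs["L2"].p, 8),
            ]
        )
        assert triple[0] == 2.0  # both loci show two alleles
        assert triple[1] == pytest.approx(he, abs=1e-12)
        assert triple[2] == pytest.approx(hd.temporal_f(base, freqs), abs=1e-12)

    def test_sample_loci_must_be_subset_of_base(self):
        base = hd.table_from_frequencies({"LX": ([1], [1.0])})
        ds = hd.read_genotypes("sample_id\tpopulation_id\tL1\ns\tg\t100/100\n")
        with pytest.raises(ValueError):
            hd.summarize_sample(ds, base)


@pytest.fixture(scope="module")
def small_problem():
    base, _ = hd.make_founder_population(hd.FounderSpec(n_loci=12, seed=21))
    series = hd.drift_series(base, 150, [(5, 24), (10, 24), (32, 24)], seed=22)
    obs = observed_summaries(series, base)
    return base, obs


class TestRejection:
    def test_accept_all_limit_recovers_prior(self, small_problem):
        base, obs = small_problem
        res = hd.abc_rejection(
            obs, base, iterations=20_000, epsilon=1e6, seed=1, batch_size=10_000
        )
        assert res.acceptance_rate == 1.0
        se = res.accepted.std(ddof=1) / np.sqrt(res.accepted.size)
        assert abs(res.posterior_mean - 500.0) < 3 * se + 0.5  # + rounding-to-int slack

    def test_zero_tolerance_fails_explicitly(self, small_problem):
        base, obs = small_problem
        with pytest.raises(AcceptanceFailure, match="epsilon"):
            hd.abc_rejection(obs, base, iterations=500, epsilon=1e-9, seed=2)

    def test_zero_valued_observation_demands_absolute_distance(self):
        base, ds = _monomorphic_pair()
        obs = np.array([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="absolute"):
            hd.abc_rejection(
                obs, base, generations=(5,), sample_sizes=(24,), iterations=10, seed=0
            )
        res = hd.abc_rejection(
            obs,
            base,
            generations=(5,),
            sample_sizes=(24,),
            iterations=200,
            epsilon=0.5,
            distance="absolute",
            seed=0,
        )
        assert res.acceptance_rate == 1.0  # monomorphic forward model matches exactly

    def test_seed_reproducibility(self, small_problem):
        base, obs = small_problem
        kw = dict(iterations=4000, epsilon=0.5, seed=7)
        a = hd.abc_rejection(obs, base, **kw)
        b = hd.abc_rejection(obs, base, **kw)
        assert np.array_equal(a.accepted, b.accepted)

    def test_acceptance_rate_nondecreasing_in_epsilon(self, small_problem):
        base, obs = small_problem
        rates = [
            hd.abc_rejection(obs, base, iterations=4000, epsilon=eps, seed=11).acceptance_rate
            for eps in (0.15, 0.3, 0.6)
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_posterior_concentrates_with_smaller_tolerance(self, small_problem):
        base, obs = small_problem
        wide = hd.abc_rejection(obs, base, iterations=30_000, target_rate=0.1, seed=13)
        tight = hd.abc_rejection(obs, base, iterations=30_000, target_rate=0.004, seed=13)
        iqr = lambda a: np.subtract(*np.percentile(a, [75, 25]))
        assert iqr(tight.accepted) < iqr(wide.accepted)

    def test_strong_drift_pulls_posterior_down(self):
        base, _ = hd.make_founder_population(hd.FounderSpec(n_loci=12, seed=31))
        obs_small = observed_summaries(hd.drift_series(base, 40, seed=32), base)
        obs_large = observed_summaries(hd.drift_series(base, 800, seed=33), base)
        kw = dict(iterations=15_000, target_rate=0.01, seed=34)
        lo = hd.abc_rejection(obs_small, base, **kw)
        hi = hd.abc_rejection(obs_large, base, **kw)
        assert np.median(lo.accepted) < np.median(hi.accepted)


class TestModelInterface:
    def test_from_samples_and_fit_summary(self, small_problem):
        base, _ = small_problem
        series = hd.drift_series(base, 150, [(5, 24), (10, 24), (32, 24)], seed=41)
        model = hd.TemporalNeABC.from_samples(base, series)
        assert model.generations == (5, 10, 32)
        assert model.sample_sizes == (24, 24, 24)
        res = model.fit(iterations=5000, target_rate=0.02, seed=42)
        text = res.summary()
        assert "posterior mean" in text and "accepted" in text
        lo, hi = res.credible_interval(0.9)
        assert 0 <= lo <= res.posterior_mean <= 1000 and lo < hi

    def test_posterior_density_integrates_to_about_one(self, small_problem):
        base, obs = small_problem
        res = hd.abc_rejection(obs, base, iterations=5000, target_rate=0.05, seed=43)
        grid, dens = res.posterior_density()
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.06)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hd.ABCConfig(epsilon=-1.0)
        with pytest.raises(ValueError):
            hd.ABCConfig(generations=(10, 5, 32))
        with pytest.raises(ValueError):
            hd.ABCConfig(sample_sizes=(24, 24))


def test_drift_series_alleles_never_leave_base_set():
    """No mutation in the forward model: sampled alleles stay within the
    founder allele set of each locus."""
    base, _ = hd.make_founder_population(hd.FounderSpec(n_loci=8, seed=51))
    series = hd.drift_series(base, 30, [(5, 10), (32, 10)], seed=52)
    for ds in series.values():
        for j, locus in enumerate(ds.loci):
            allowed = set(base[locus].labels.tolist())
            for row in ds.calls:
                if row[j] is not None:
                    assert set(row[j]) <= allowed
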