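import numpy as np
import pandas as pd
import pytest

import haplodrift as hd

TOY_GENOTYPES = """sample_id\tpopulation_id\tL1\tL2
a1\tpopA\t100/102\t120/120
a2\tpopA\t100/100\t120/124
b1\tpopB\t102/102\t124/124
b2\tpopB\t100/102\tNA
"""


@pytest.fixture
def toy_dataset() -> hd.GenotypeDataset:
    return hd.read_genotypes(TOY_GENOTYPES)


@pytest.fixture(scope="session")
def founder():
    """A 40-locus founder panel: (frequency table, genotyped sample)."""
    return hd.make_founder_population(hd.FounderSpec(seed=11))


@pytest.fixture(scope="session")
def six_site_table() -> pd.DataFrame:
    """Toy SNP table: one site fails each filter rule, two pass."""
    rows = [
        ("1", 100, "A", 20, (15, 5), 19.0, 30.0),   # consensus quality below 20
        ("1", 200, "C", 20, (15, 5), 30.0, 19.0),   # mapping quality below 20
        ("1", 300, "G", 7, (5, 2), 30.0, 30.0),     # coverage below 8
        ("1", 400, "T", 20, (19, 1), 30.0, 30.0),   # minor-allele count below 2
        ("1", 500, "A", 8, (6, 2), 20.0, 20.0),     # passes, every rule at threshold
        ("1", 600, "C", 32, (30, 2), 30.0, 30.0),   # passes
    ]
    return pd.DataFrame(rows, columns=hd.poolseq.SITE_COLUMNS)


def make_two_pop_table(rng: np.random.Generator, n_per_pop: int = 8, n_loci: int = 5):
    """Two samples drawn from one homogeneous population (null F_ST)."""
    labels = np.array([100, 102, 104])
    p = np.array([0.5, 0.3, 0.2])
    samples, calls = [], []
    for pop in ("x", "y"):
        for i in range(n_per_pop):
            samples.append((f"{pop}{i}", pop))
            calls.append(
                [tuple(sorted(rng.choice(labels, size=2, p=p))) for _ in range(n_loci)]
            )
    return hd.GenotypeDataset(
        samples=samples, loci=[f"L{j}" for j in range(n_loci)], calls=calls
    )
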