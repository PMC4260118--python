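"""Multilocus diploid genotype tables and allele-frequency derivation.

The package's native genotype format is a delimited text table (tab or
comma) with a header row::

    sample_id  population_id  Nv101  Nv204  ...
    f01        gen5           100/102  98/98
    f02        gen5           NA       98/104

Each locus column holds one diploid call as two integer allele labels
joined by ``/`` (microsatellite fragment lengths, treated as opaque
integers), or the missing token ``NA``.  All genotyped individuals are
diploid females; haploid males never appear in genotype files.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING_TOKEN = "NA"

__all__ = [
    "GenotypeParseError",
    "GenotypeValidationError",
    "LocusFrequencies",
    "AlleleFrequencyTable",
    "GenotypeDataset",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
]


class GenotypeParseError(ValueError):
    """Malformed genotype file (reported with the offending line number)."""


class GenotypeValidationError(ValueError):
    """Structurally valid file that violates a dataset invariant."""


@dataclass(frozen=True)
class LocusFrequencies:
    """Allele frequencies at one locus.

    Parameters
    ----------
    labels : ndarray of int
        Allele labels, ascending.
    p : ndarray of float
        Relative frequencies, summing to 1 over the observed alleles.
    m : int or None
        Gene-copy count behind the estimate (2 x genotyped individuals).
        ``None`` marks a theoretical (population) frequency vector, e.g.
        a simulated founder pool, where no finite sample underlies ``p``.
    """

    labels: np.ndarray
    p: np.ndarray
    m: int | None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        p = np.asarray(self.p, dtype=float)
        if labels.shape != p.shape or labels.ndim != 1 or labels.size == 0:
            raise GenotypeValidationError("labels and p must be equal-length 1-D arrays")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise GenotypeValidationError("allele frequencies must be non-negative and sum to 1")
        if self.m is not None and (self.m < 2 or self.m % 2):
            raise GenotypeValidationError("gene-copy count m must be an even integer >= 2")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "p", p)

    def frequency(self, label: int) -> float:
        idx = np.flatnonzero(self.labels == label)
        return float(self.p[idx[0]]) if idx.size else 0.0


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequency vectors, keyed by locus name (ordered)."""

    loci: dict[str, LocusFrequencies]

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    def items(self):
        return self.loci.items()

    def to_frame(self):
        """Long-format table: one row per (locus, allele)."""
        import pandas as pd

        rows = [
            {"locus": name, "allele": int(a), "frequency": float(f), "m": lf.m}
            for name, lf in self.loci.items()
            for a, f in zip(lf.labels, lf.p)
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "frequency", "m"])


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes grouped into population samples.

    ``calls[i][j]`` is the unordered pair of integer allele labels for
    sample ``i`` at locus ``j`` (stored as a sorted tuple), or ``None``
    when missing.
    """

    samples: list[tuple[str, str]]
    loci: list[str]
    calls: list[list[tuple[int, int] | None]] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.loci:
            raise GenotypeValidationError("dataset has zero loci")
        if not self.samples:
            raise GenotypeValidationError("dataset has zero samples")
        ids = [sid for sid, _ in self.samples]
        dup = [s for s, k in Counter(ids).items() if k > 1]
        if dup:
            raise GenotypeValidationError(f"duplicate sample_id: {dup[0]!r}")
        if len(self.calls) != len(self.samples):
            raise GenotypeValidationError("calls and samples differ in length")
        norm: list[list[tuple[int, int] | None]] = []
        for (sid, _), row in zip(self.samples, self.calls):
            if len(row) != len(self.loci):
                raise GenotypeValidationError(
                    f"sample {sid!r} has {len(row)} calls for {len(self.loci)} loci"
                )
            nrow: list[tuple[int, int] | None] = []
            for call in row:
                if call is None:
                    nrow.append(None)
                else:
                    a, b = call
                    nrow.append((int(a), int(b)) if a <= b else (int(b), int(a)))
            norm.append(nrow)
        self.calls = norm

    # -- views ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pop in self.samples:
            seen.setdefault(pop)
        return list(seen)

    def population_indices(self, population: str) -> list[int]:
        idx = [i for i, (_, pop) in enumerate(self.samples) if pop == population]
        if not idx:
            raise KeyError(f"unknown population_id: {population!r}")
        return idx

    def subset(self, population: str) -> "GenotypeDataset":
        idx = self.population_indices(population)
        return GenotypeDataset(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            calls=[list(self.calls[i]) for i in idx],
        )

    @staticmethod
    def concat(datasets: Sequence["GenotypeDataset"]) -> "GenotypeDataset":
        """Stack datasets sharing an identical locus panel."""
        loci = datasets[0].loci
        for ds in datasets[1:]:
            if ds.loci != loci:
                raise GenotypeValidationError("datasets differ in locus panel")
        return GenotypeDataset(
            samples=[s for ds in datasets for s in ds.samples],
            loci=list(loci),
            calls=[list(r) for ds in datasets for r in ds.calls],
        )


# ---------------------------------------------------------------------------
# reading / writing


def _split_header(line: str) -> tuple[list[str], str]:
    sep = "\t" if "\t" in line else ","
    return [t.strip() for t in line.rstrip("\n").split(sep)], sep


def read_genotypes(source, dialect: str = "slash") -> GenotypeDataset:
    """Read the delimited genotype format.

    Parameters
    ----------
    source : path, str of content with newlines, or text stream.
    dialect : {"slash"}
        Only the native slash-joined-pair dialect is implemented.
    """
    if dialect != "slash":
        raise ValueError(f"unknown genotype dialect: {dialect!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        src = str(source)
        text = Path(src).read_text() if "\n" not in src else src
    lines = [ln for ln in io.StringIO(text)]
    if not lines:
        raise GenotypeParseError("empty genotype file")
    header, sep = _split_header(lines[0])
    if len(header) < 3 or header[0] != "sample_id" or header[1] != "population_id":
        raise GenotypeParseError(
            "header must start with 'sample_id', 'population_id' and at least one locus"
        )
    loci = header[2:]
    samples: list[tuple[str, str]] = []
    calls: list[list[tuple[int, int] | None]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = [t.strip() for t in raw.rstrip("\n").split(sep)]
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row: list[tuple[int, int] | None] = []
        for locus, tok in zip(loci, fields[2:]):
            if tok == MISSING_TOKEN:
                row.append(None)
                continue
            parts = tok.split("/")
            if len(parts) != 2:
                raise GenotypeParseError(
                    f"line {lineno}: call {tok!r} at locus {locus!r} does not have "
                    "exactly two allele fields"
                )
            try:
                row.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise GenotypeParseError(
                    f"line {lineno}: non-integer allele in call {tok!r} at locus {locus!r}"
                ) from exc
        samples.append((fields[0], fields[1]))
        calls.append(row)
    return GenotypeDataset(samples=samples, loci=loci, calls=calls)


def write_genotypes(dataset: GenotypeDataset, dest) -> None:
    """Write a dataset in the native tab-delimited format (round-trip safe)."""
    out = ["\t".join(["sample_id", "population_id", *dataset.loci])]
    for (sid, pop), row in zip(dataset.samples, dataset.calls):
        toks = [MISSING_TOKEN if c is None else f"{c[0]}/{c[1]}" for c in row]
        out.append("\t".join([sid, pop, *toks]))
    text = "\n".join(out) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(dataset: GenotypeDataset, population: str) -> AlleleFrequencyTable:
    """Per-locus allele frequencies by gene counting over non-missing calls.

    Loci where every call in the population is missing are omitted from
    the table, with a warning.
    """
    idx = dataset.population_indices(population)
    loci: dict[str, LocusFrequencies] = {}
    for j, locus in enumerate(dataset.loci):
        counts: Counter[int] = Counter()
        for i in idx:
            call = dataset.calls[i][j]
            if call is not None:
                counts[call[0]] += 1
                counts[call[1]] += 1
        if not counts:
            warnings.warn(
                f"locus {locus!r}: all calls missing in population {population!r}; omitted",
                stacklevel=2,
            )
            continue
        labels = np.array(sorted(counts), dtype=int)
        m = sum(counts.values())
        p = np.array([counts[a] for a in labels], dtype=float) / m
        loci[locus] = LocusFrequencies(labels=labels, p=p, m=m)
    return AlleleFrequencyTable(loci=loci)


def table_from_frequencies(
    freqs: Mapping[str, tuple[Iterable[int], Iterable[float]]],
    m: int | None = None,
) -> AlleleFrequencyTable:
    """Build a table from explicit {locus: (labels, p)} mappings."""
    loci = {
        name: LocusFrequencies(np.asarray(lab, dtype=int), np.asarray(p, dtype=float), m)
        for name, (lab, p) in freqs.items()
    }
    return AlleleFrequencyTable(loci=loci)
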