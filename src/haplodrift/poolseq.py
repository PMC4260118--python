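"""Pool-seq SNP filtering and 100-kb window diversity summaries.

Sites come in as a delimited "sync-like" text table, one row per
candidate SNP::

    chrom  pos  ref  depth  counts  cons_qual  map_qual
    1      512  A    42     30,12   38         55

``pos`` is 1-based; ``counts`` are comma-separated per-allele read
counts (major first by convention, but only their order statistics
matter).  Filtering retains sites passing the classic pooled-variant
rules: consensus quality, mapping quality, a coverage floor and
ceiling, and a minimum minor-allele read count (all thresholds
inclusive).

Window analysis tiles each chromosome into nonoverlapping half-open
windows (default 100 kb, the last window may be short) and reports SNP
counts, mean read depth, read-depth-adjusted SNP density, the fraction
of positions whose depth falls inside the coverage bounds, and the
per-base-pair nucleotide diversity

    pi = sum_sites (d/(d-1)) * (1 - sum_a (c_a/d)^2)  /  (qualifying positions)

which is only reported when the qualifying-coverage fraction of the
window reaches the configured minimum (default 0.6).  The per-site term
is a simplified unbiased heterozygosity; it matches the structure, not
the exact correction terms, of pooled-resequencing pipeline estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "SiteRecord",
    "read_sites",
    "write_sites",
    "filter_sites",
    "window_summaries",
    "chromosome_means",
    "snp_spacing",
]

SITE_COLUMNS = ["chrom", "pos", "ref", "depth", "counts", "cons_qual", "map_qual"]


@dataclass(frozen=True)
class FilterConfig:
    """SNP filter thresholds and window-analysis settings (all inclusive)."""

    min_cons_qual: float = 20.0
    min_minor_count: int = 2
    min_coverage: int = 8
    min_map_qual: float = 20.0
    max_coverage: int = 1_000_000
    min_window_cov_fraction: float = 0.6
    window_size: int = 100_000

    def __post_init__(self) -> None:
        if min(self.min_cons_qual, self.min_minor_count, self.min_coverage,
               self.min_map_qual, self.max_coverage) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.window_size < 1:
            raise ValueError("window size must be >= 1 bp")
        if not 0.0 <= self.min_window_cov_fraction <= 1.0:
            raise ValueError("coverage fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SiteRecord:
    """One candidate SNP site (1-based position)."""

    chrom: str
    pos: int
    ref: str
    depth: int
    counts: tuple[int, ...]
    cons_qual: float
    map_qual: float

    def __post_init__(self) -> None:
        if self.pos < 1 or self.depth < 0:
            raise ValueError("position must be >= 1 and depth >= 0")
        if len(self.counts) < 2:
            raise ValueError("a site needs at least two allele counts")
        if sum(self.counts) > self.depth:
            raise ValueError("allele counts exceed read depth")


def sites_frame(records) -> pd.DataFrame:
    """DataFrame view of an iterable of SiteRecord."""
    return pd.DataFrame(
        [
            (r.chrom, r.pos, r.ref, r.depth, tuple(r.counts), r.cons_qual, r.map_qual)
            for r in records
        ],
        columns=SITE_COLUMNS,
    )


def read_sites(source) -> pd.DataFrame:
    """Read the delimited site table (tab-separated, with header)."""
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table lacks columns: {missing}")
    df["counts"] = df["counts"].map(
        lambda s: tuple(int(t) for t in str(s).split(","))
    )
    return df[SITE_COLUMNS]


def write_sites(sites: pd.DataFrame, dest) -> None:
    out = sites.copy()
    out["counts"] = out["counts"].map(lambda c: ",".join(str(int(x)) for x in c))
    out.to_csv(dest, sep="\t", index=False)


def _validate_sorted(sites: pd.DataFrame) -> None:
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"chromosome {chrom}: positions not sorted/unique")


def filter_sites(sites: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the SNP filter rules; order preserved, index reset."""
    cfg = cfg or FilterConfig()
    _validate_sorted(sites)
    minor = sites["counts"].map(lambda c: sorted(c)[-2])
    keep = (
        (sites["cons_qual"] >= cfg.min_cons_qual)
        & (sites["map_qual"] >= cfg.min_map_qual)
        & (sites["depth"] >= cfg.min_coverage)
        & (sites["depth"] <= cfg.max_coverage)
        & (minor >= cfg.min_minor_count)
    )
    return sites.loc[keep].reset_index(drop=True)


def _pi_site(depth: int, counts) -> float:
    if depth < 2:
        return 0.0
    freqs = np.asarray(counts, dtype=float) / depth
    return depth / (depth - 1) * (1.0 - float(np.sum(freqs**2)))


def window_summaries(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    depth_track: Mapping[str, np.ndarray] | None = None,
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Nonoverlapping window summaries over filtered sites.

    Windows are half-open 0-based intervals [k*w, (k+1)*w) tiling each
    chromosome in ``chrom_lengths``; a site at 1-based position p falls
    in the window containing p-1.  ``depth_track`` maps chromosome to a
    per-base depth array (index 0 = position 1); when absent, mean depth
    and the coverage fraction are approximated from the depths of the
    SNP sites themselves and the approximation is marked in the
    ``depth_from_track`` column.
    """
    cfg = cfg or FilterConfig()
    _validate_sorted(sites)
    unknown = set(sites["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"sites on chromosomes without a length: {sorted(unknown)}")
    rows = []
    w = cfg.window_size
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        if len(sub) and sub["pos"].max() > length:
            raise ValueError(f"chromosome {chrom}: site beyond stated length {length}")
        n_windows = max(1, math.ceil(length / w))
        widx = (sub["pos"].to_numpy() - 1) // w if len(sub) else np.array([], dtype=int)
        track = depth_track.get(chrom) if depth_track is not None else None
        if track is not None and len(track) < length:
            raise ValueError(f"depth track for {chrom} shorter than chromosome")
        for k in range(n_windows):
            start, end = k * w, min((k + 1) * w, length)
            in_win = sub.iloc[np.flatnonzero(widx == k)]
            n_snps = len(in_win)
            pi_sum = float(
                sum(_pi_site(d, c) for d, c in zip(in_win["depth"], in_win["counts"]))
            )
            if track is not None:
                seg = np.asarray(track[start:end])
                covered = seg > 0
                mean_depth = float(seg[covered].mean()) if covered.any() else np.nan
                qualify = (seg >= cfg.min_coverage) & (seg <= cfg.max_coverage)
                cov_fraction = float(qualify.mean())
                n_qualifying = int(qualify.sum())
            else:
                depths = in_win["depth"].to_numpy()
                if depths.size:
                    mean_depth = float(depths.mean())
                    cov_fraction = float(
                        ((depths >= cfg.min_coverage) & (depths <= cfg.max_coverage)).mean()
                    )
                else:
                    mean_depth, cov_fraction = np.nan, 0.0
                n_qualifying = int(round(cov_fraction * (end - start)))
            density_ok = np.isfinite(mean_depth) and mean_depth >= cfg.min_coverage
            adj_density = n_snps / mean_depth if density_ok else np.nan
            pi_defined = (
                cov_fraction >= cfg.min_window_cov_fraction and n_qualifying > 0
            )
            pi = pi_sum / n_qualifying if pi_defined else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": n_snps,
                    "mean_depth": mean_depth,
                    "adj_density": adj_density,
                    "cov_fraction": cov_fraction,
                    "pi": pi,
                    "pi_defined": pi_defined,
                    "depth_from_track": track is not None,
                }
            )
    return pd.DataFrame(rows)


def chromosome_means(windows: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome (and overall) mean and SE of the window summaries.

    Densities average over windows where the depth floor was met;
    nucleotide diversity over windows where pi is defined.
    """

    def _agg(grp: pd.DataFrame) -> dict:
        out = {"n_windows": len(grp)}
        for col, name in [
            ("n_snps", "snp_density"),
            ("adj_density", "adj_density"),
            ("mean_depth", "depth"),
            ("pi", "pi"),
        ]:
            v = grp[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            out[f"mean_{name}"] = v.mean() if v.size else np.nan
            out[f"se_{name}"] = (
                v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else np.nan
            )
        return out

    rows = [{"chrom": c, **_agg(g)} for c, g in windows.groupby("chrom", sort=False)]
    rows.append({"chrom": "All", **_agg(windows)})
    return pd.DataFrame(rows)


def snp_spacing(n_snps: int, genome_size: int) -> float:
    """Mean base pairs per SNP, rounded to one decimal."""
    if n_snps < 1 or genome_size < 1:
        raise ValueError("n_snps and genome_size must be >= 1")
    return round(genome_size / n_snps, 1)
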