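"""CpG methylation levels over intervals, promoters and region profiles.

Bisulfite calls arrive as per-CpG methylated / unmethylated counts.  The
methylation level of an interval is the coverage-weighted pooled ratio

    level = sum(methylated) / sum(methylated + unmethylated)

over contained CpGs, which is robust at the low per-CpG coverage of
ultra-low-input bisulfite data.  The unweighted mean of per-CpG ratios is
available behind ``per_cpg_mean=True``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout


@dataclass
class CpGCallSet:
    """Per-CpG counts: columns chrom, pos (0-based), strand, meth, unmeth."""

    calls: pd.DataFrame

    REQUIRED = ("chrom", "pos", "strand", "meth", "unmeth")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.calls.columns:
                raise ValueError(f"CpG calls missing column {col!r}")
        if len(self.calls) and (
            (self.calls["meth"] < 0).any() or (self.calls["unmeth"] < 0).any()
        ):
            raise ValueError("negative CpG counts")
        if self.calls.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate CpG positions per (chrom, strand)")
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, sub in self.calls.groupby("chrom", sort=False):
            self._by_chrom[chrom] = sub.sort_values("pos")

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def coverage(self) -> pd.Series:
        return self.calls["meth"] + self.calls["unmeth"]

    def in_interval(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        sub = self._by_chrom.get(chrom)
        if sub is None:
            return pd.DataFrame(columns=list(self.REQUIRED))
        pos = sub["pos"].to_numpy()
        i0 = np.searchsorted(pos, start, "left")
        i1 = np.searchsorted(pos, end, "left")
        return sub.iloc[i0:i1]


@dataclass
class MethLevel:
    """Pooled methylation of one interval; ``level`` is NaN when no CpG qualifies."""

    chrom: str
    start: int
    end: int
    meth: int
    total: int
    n_cpgs: int
    level: float = field(init=False)

    def __post_init__(self) -> None:
        self.level = self.meth / self.total if self.total > 0 else float("nan")

    @property
    def defined(self) -> bool:
        return self.total > 0


def read_cpg_calls(path) -> CpGCallSet:
    """Read a cytosine report: chrom, 1-based position, strand, meth, unmeth.

    Positions convert to the internal 0-based frame.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{i}: expected 5 tab-separated fields")
            try:
                rows.append(
                    (parts[0], int(parts[1]) - 1, parts[2], int(parts[3]), int(parts[4]))
                )
            except ValueError as err:
                raise ValueError(f"{path}:{i}: {err}") from None
    return CpGCallSet(
        pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    )


def write_cpg_calls(calls: CpGCallSet, path) -> None:
    """Write calls back out with 1-based positions (inverse of read_cpg_calls)."""
    with open(path, "w") as fh:
        for row in calls.calls.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.meth}\t{row.unmeth}\n")


def meth_level(
    calls: CpGCallSet,
    intervals,
    min_cov: int = 1,
    per_cpg_mean: bool = False,
) -> list[MethLevel]:
    """Methylation level per (chrom, start, end) interval.

    CpGs with coverage below ``min_cov`` are excluded.  Intervals with no
    qualifying CpG report an undefined level (NaN), never 0.
    """
    out = []
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        sub = calls.in_interval(chrom, start, end)
        cov = (sub["meth"] + sub["unmeth"]).to_numpy()
        keep = cov >= min_cov
        meth = int(sub["meth"].to_numpy()[keep].sum())
        total = int(cov[keep].sum())
        lvl = MethLevel(chrom, start, end, meth, total, int(keep.sum()))
        if per_cpg_mean and lvl.n_cpgs:
            ratios = sub["meth"].to_numpy()[keep] / cov[keep]
            lvl.level = float(ratios.mean())
        out.append(lvl)
    return out


def promoter_meth_by_cgi(
    calls: CpGCallSet,
    tss_list,
    cgi_intervals,
    half_width: int = 5_000,
    layout: GenomeLayout | None = None,
    min_cov: int = 1,
    per_cpg_mean: bool = False,
) -> tuple[list[MethLevel], list[MethLevel]]:
    """Promoter methylation split by CpG-island overlap.

    Promoters are ``[TSS - half_width, TSS + half_width)`` clipped to the
    chromosome; a promoter is "with CGI" iff it overlaps any CGI interval
    by at least 1 bp (half-open, so an exactly abutting CGI does not
    count).  Returns (with_cgi, without_cgi) level lists.
    """
    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in cgi_intervals:
        cgi_by_chrom.setdefault(chrom, []).append((start, end))
    with_cgi, without_cgi = [], []
    for chrom, pos, _strand in tss_list:
        start, end = pos - half_width, pos + half_width
        if layout is not None:
            start = max(0, start)
            end = min(layout.length_of(chrom), end)
        overlaps = any(s < end and start < e for s, e in cgi_by_chrom.get(chrom, []))
        (with_cgi if overlaps else without_cgi).append(
            meth_level(calls, [(chrom, start, end)], min_cov, per_cpg_mean)[0]
        )
    return with_cgi, without_cgi


def region_meth_profile(
    calls: CpGCallSet,
    regions,
    flank: int = 100_000,
    body_bins: int = 100,
    flank_bins: int = 50,
    layout: GenomeLayout | None = None,
    min_cov: int = 1,
) -> np.ndarray:
    """Per-bin pooled methylation across regions, on the meta-profile axis.

    Same binning scheme as the ChIP region meta-profile (fixed-width flank
    bins, body rescaled to ``body_bins``).  Counts pool across features per
    bin; bins with zero qualifying CpGs (or clipped off the chromosome) are
    NaN.
    """
    from .chip import _profile_edges_region  # shared bin geometry

    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    n_bins = 2 * flank_bins + body_bins
    meth_sum = np.zeros(n_bins)
    total_sum = np.zeros(n_bins)
    for chrom, start, end in regions:
        chrom_len = layout.length_of(chrom) if layout is not None else None
        edges = _profile_edges_region(start, end, flank, body_bins, flank_bins)
        for j, (s, e) in enumerate(edges):
            if s < 0 or (chrom_len is not None and e > chrom_len):
                continue  # clipped bin: contributes nothing
            sub = calls.in_interval(chrom, int(np.ceil(s)), int(np.ceil(e)))
            cov = (sub["meth"] + sub["unmeth"]).to_numpy()
            keep = cov >= min_cov
            meth_sum[j] += sub["meth"].to_numpy()[keep].sum()
            total_sum[j] += cov[keep].sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.where(total_sum > 0, meth_sum / np.maximum(total_sum, 1), np.nan)
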