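"""Count containers and expression normalization (RPM, FPKM, VST).

The count unit shared by genes, sliding windows and repeat elements is a
``CountMatrix``: a features x samples table of non-negative integers with
per-sample group / replicate / library-size metadata.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Window

SAMPLE_COLUMNS = ("group", "replicate", "library_size")


@dataclass
class CountMatrix:
    """Raw counts (features x samples) plus sample metadata.

    ``samples`` is indexed by sample id and carries ``group`` (condition
    label), ``replicate`` (integer within group) and ``library_size``
    (total mapped reads used for depth normalization).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata index disagree")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.samples["library_size"] <= 0).any():
            raise ValueError("every sample needs library_size > 0")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        ids = self.samples.index[self.samples["group"] == group]
        if len(ids) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return list(ids)

    def group_counts(self, group: str) -> pd.DataFrame:
        return self.counts[self.samples_in_group(group)]

    def library_sizes(self, group: str) -> np.ndarray:
        return self.samples.loc[self.samples_in_group(group), "library_size"].to_numpy(float)

    def pooled(self, group: str) -> tuple[pd.Series, float]:
        """Replicate-pooled counts and pooled library size for a group."""
        ids = self.samples_in_group(group)
        return self.counts[ids].sum(axis=1), float(self.samples.loc[ids, "library_size"].sum())


@dataclass
class ExpressionTable:
    """Normalized expression values with a fixed unit tag (RPM, FPKM or VST)."""

    values: pd.DataFrame
    unit: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.unit not in ("RPM", "FPKM", "VST", "NORM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit in ("RPM", "FPKM", "NORM") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")

    def group_means(self, group: str) -> pd.Series:
        ids = self.samples.index[self.samples["group"] == group]
        if len(ids) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[list(ids)].mean(axis=1)


def count_in_intervals(
    positions: dict[str, np.ndarray], intervals: list[Window], layout: GenomeLayout | None = None
) -> np.ndarray:
    """Count read 5' positions falling in each interval.

    A read is assigned by its single 5' position, so a read is counted once
    by every interval that contains it (overlapping sliding windows each
    count it).
    """
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in positions.items()}
    if layout is not None:
        for c, p in sorted_pos.items():
            if len(p) and (p[0] < 0 or p[-1] >= layout.length_of(c)):
                raise ValueError(f"read position off chromosome {c!r}")
    out = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        if layout is not None:
            layout.check_interval(iv.chrom, iv.start, iv.end)
        p = sorted_pos.get(iv.chrom)
        if p is None:
            continue
        out[i] = np.searchsorted(p, iv.end, "left") - np.searchsorted(p, iv.start, "left")
    return out


def rpm(count, library_size):
    """Reads per million mapped reads: ``count * 1e6 / library_size``."""
    library_size = np.asarray(library_size, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be > 0")
    return np.asarray(count, dtype=float) * 1e6 / library_size


def fpkm(count, feature_length, library_size):
    """Fragments per kilobase per million: ``count * 1e9 / (length * library_size)``."""
    feature_length = np.asarray(feature_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(feature_length <= 0):
        raise ValueError("feature_length must be > 0")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be > 0")
    return np.asarray(count, dtype=float) * 1e9 / (feature_length * library_size)


def rpm_table(matrix: CountMatrix) -> ExpressionTable:
    sizes = matrix.samples["library_size"].to_numpy(float)
    values = matrix.counts.astype(float) * 1e6 / sizes
    return ExpressionTable(values, "RPM", matrix.samples)


def fpkm_table(matrix: CountMatrix, feature_lengths: pd.Series) -> ExpressionTable:
    lengths = feature_lengths.reindex(matrix.counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise KeyError(f"feature lengths missing for {missing} ...")
    sizes = matrix.samples["library_size"].to_numpy(float)
    values = matrix.counts.astype(float) * 1e9 / sizes
    values = values.div(lengths.astype(float), axis=0)
    return ExpressionTable(values, "FPKM", matrix.samples)


def size_factors(counts: pd.DataFrame, library_sizes: np.ndarray | None = None) -> np.ndarray:
    """Median-of-ratios size factors over features with all-positive counts.

    When no feature is positive in every sample, falls back to library-size
    ratios (each size divided by the mean size).
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0 or not np.any(x > 0):
        raise ValueError("all-zero count matrix")
    allpos = np.all(x > 0, axis=1)
    if allpos.any():
        logx = np.log(x[allpos])
        ref = logx.mean(axis=1)  # log geometric mean per feature
        return np.exp(np.median(logx - ref[:, None], axis=0))
    if library_sizes is None:
        raise ValueError("no all-positive feature and no library sizes for fallback")
    sizes = np.asarray(library_sizes, dtype=float)
    return sizes / sizes.mean()


def vst(matrix: CountMatrix) -> ExpressionTable:
    """Variance-stabilized expression: ``log2(count / size_factor + 1)``.

    Size factors come from the median-of-ratios estimator; the shifted-log
    transform is strictly increasing in the count for a fixed size factor
    and flattens the mean-variance trend of overdispersed counts.
    """
    sf = size_factors(matrix.counts, matrix.samples["library_size"].to_numpy(float))
    values = np.log2(matrix.counts.astype(float) / sf + 1.0)
    return ExpressionTable(values, "VST", matrix.samples)


def mor_table(matrix: CountMatrix) -> ExpressionTable:
    """Size-factor-normalized counts (median-of-ratios), unit tag NORM.

    Unlike RPM/FPKM this normalization is robust to composition shifts such
    as the burst of transcription at embryonic genome activation, where a
    large gene set rises in one direction and inflates the library size;
    it is the scale on which classification fold changes are computed.
    """
    sf = size_factors(matrix.counts, matrix.samples["library_size"].to_numpy(float))
    return ExpressionTable(matrix.counts.astype(float) / sf, "NORM", matrix.samples)


def delog_vst(values: pd.DataFrame) -> pd.DataFrame:
    """Inverse of the VST shifted-log: ``2**v - 1`` (size-factor-scaled counts)."""
    return 2.0**values - 1.0
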