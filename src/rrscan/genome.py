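"""Genome coordinate frame: chromosome layout and sliding windows.

All coordinates are 0-based half-open internally.  Readers for 1-based
formats (GTF, CpG reports) convert at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import pandas as pd


class Window(NamedTuple):
    """A genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Ordered chromosome names with lengths in bp.

    Insertion order is the genome order used for all interval output.
    """

    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        return self.sizes[chrom]

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.sizes[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome of "
                f"length {self.sizes[chrom]}"
            )

    def iter_chroms(self) -> Iterator[tuple[str, int]]:
        return iter(self.sizes.items())


def make_windows(layout: GenomeLayout, size: int = 50_000, step: int = 20_000) -> list[Window]:
    """Tile every chromosome with sliding windows of ``size`` bp every ``step`` bp.

    Windows start at 0, step, 2*step, ... and only full-size windows are
    emitted: a start qualifies iff ``start + size <= chrom length``.  Partial
    terminal windows are dropped so every emitted window has exactly ``size``
    bp, which keeps the minimum merged-region length equal to the window size.
    """
    if len(layout) == 0:
        raise ValueError("empty genome layout")
    if not (0 < step <= size):
        raise ValueError(f"require 0 < step <= size, got step={step}, size={size}")
    windows: list[Window] = []
    for chrom, length in layout.iter_chroms():
        start = 0
        while start + size <= length:
            windows.append(Window(chrom, start, start + size))
            start += step
    return windows


def windows_to_frame(windows: list[Window]) -> pd.DataFrame:
    """Windows as a BED-like DataFrame with a stable ``window_id`` index."""
    df = pd.DataFrame(windows, columns=["chrom", "start", "end"])
    df.index = pd.Index(
        [f"{w.chrom}:{w.start}-{w.end}" for w in windows], name="window_id"
    )
    return df


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return GenomeLayout(sizes)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.iter_chroms():
            fh.write(f"{chrom}\t{length}\n")
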