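"""Input-normalized ChIP intensities and meta-profiles.

Coverage lives on a fixed genome binning (default 200 bp).  The intensity
of an interval is the log2 ratio of depth- and length-normalized ChIP
density over matched input density, which makes it invariant to sequencing
depth and symmetric around zero:

    d = RPM(reads in interval) / length_kb          [RPM per kb]
    intensity = log2((d_chip + eps) / (d_input + eps)),  eps = 0.1
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import significance_stars, two_group_t
from .genome import GenomeLayout

DEFAULT_BIN_WIDTH = 200
DENSITY_EPS = 0.1  # RPM per kb


@dataclass
class SignalTrack:
    """Binned per-base coverage for one ChIP or input sample."""

    bins: dict[str, np.ndarray]  # chrom -> per-bin read counts
    bin_width: int
    library_size: float
    role: str = "chip"  # chip | input
    mark: str = ""

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for chrom, arr in self.bins.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative coverage on {chrom}")

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_width: int = DEFAULT_BIN_WIDTH, **kw) -> "SignalTrack":
        bins = {
            c: np.zeros(-(-length // bin_width), dtype=float)
            for c, length in layout.iter_chroms()
        }
        kw.setdefault("library_size", 1.0)
        return cls(bins=bins, bin_width=bin_width, **kw)

    def chrom_length(self, chrom: str) -> int:
        return len(self.bins[chrom]) * self.bin_width

    def interval_count(self, chrom: str, start: float, end: float) -> float:
        """Reads in ``[start, end)``, prorating boundary bins by overlap.

        Within-bin coverage is treated as uniform, so rebinning a track to a
        finer width leaves bin-aligned interval counts unchanged.
        """
        if end <= start:
            raise ValueError("zero-length interval")
        arr = self.bins[chrom]
        bw = self.bin_width
        i0 = int(math.floor(start / bw))
        i1 = int(math.ceil(end / bw))
        i1 = min(i1, len(arr))
        i0 = max(i0, 0)
        if i0 >= i1:
            return 0.0
        weights = np.ones(i1 - i0)
        weights[0] = (min(end, (i0 + 1) * bw) - max(start, i0 * bw)) / bw
        if i1 - i0 > 1:
            weights[-1] = (min(end, i1 * bw) - (i1 - 1) * bw) / bw
        return float(arr[i0:i1] @ weights)


def density(track: SignalTrack, chrom: str, start: float, end: float) -> float:
    """Depth- and length-normalized coverage in RPM per kb."""
    count = track.interval_count(chrom, start, end)
    length_kb = (end - start) / 1000.0
    return count * 1e6 / track.library_size / length_kb


def intensity(
    chip: SignalTrack,
    input_track: SignalTrack,
    chrom: str,
    start: float,
    end: float,
    eps: float = DENSITY_EPS,
) -> float:
    """Input-normalized log2 intensity of ``[start, end)``."""
    d_chip = density(chip, chrom, start, end)
    d_input = density(input_track, chrom, start, end)
    return float(np.log2((d_chip + eps) / (d_input + eps)))


def interval_intensities(
    chip: SignalTrack, input_track: SignalTrack, intervals, eps: float = DENSITY_EPS
) -> np.ndarray:
    """Per-interval intensities for (chrom, start, end) triples."""
    return np.array([intensity(chip, input_track, c, s, e, eps) for c, s, e in intervals])


@dataclass
class MetaProfile:
    """Per-feature intensity matrix over a shared bin axis, plus its mean.

    For region profiles the axis is ``flank_bins`` fixed-width bins, then
    ``body_bins`` body-scaled bins, then ``flank_bins`` again; for TSS
    profiles it is fixed-width bins centered on the TSS.  Bins falling off
    a chromosome end are NaN and excluded from the mean.
    """

    matrix: np.ndarray  # (n_features, n_bins), NaN = clipped bin
    flank_bins: int = 0
    body_bins: int = 0
    feature_ids: list[str] = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            return np.nanmean(self.matrix, axis=0)

    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)

    def flank_mask(self) -> np.ndarray:
        mask = np.ones(self.matrix.shape[1], dtype=bool)
        mask[self.body_slice()] = False
        return mask


def _profile_edges_region(start: float, end: float, flank: float, body_bins: int, flank_bins: int):
    fw = flank / flank_bins
    left = [(start - flank + i * fw, start - flank + (i + 1) * fw) for i in range(flank_bins)]
    bw = (end - start) / body_bins
    body = [(start + i * bw, start + (i + 1) * bw) for i in range(body_bins)]
    right = [(end + i * fw, end + (i + 1) * fw) for i in range(flank_bins)]
    return left + body + right


def _bin_intensity(chip, input_track, chrom, s, e, chrom_len, eps):
    if s < 0 or e > chrom_len:
        return np.nan  # clipped at chromosome end
    return intensity(chip, input_track, chrom, s, e, eps)


def region_metaprofile(
    chip: SignalTrack,
    input_track: SignalTrack,
    regions,
    flank: int = 100_000,
    body_bins: int = 100,
    flank_bins: int = 50,
    strands=None,
    eps: float = DENSITY_EPS,
) -> MetaProfile:
    """Scaled-body meta-profile over regions with fixed-width flanks.

    ``regions`` is an iterable of (chrom, start, end).  Each body rescales
    to ``body_bins`` equal sub-intervals; each flank is ``flank_bins`` bins
    of ``flank / flank_bins`` bp.  Minus-strand features (via ``strands``)
    are orientation-flipped so the axis always reads 5' to 3'.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    n_bins = 2 * flank_bins + body_bins
    matrix = np.full((len(regions), n_bins), np.nan)
    ids = []
    for r, (chrom, start, end) in enumerate(regions):
        ids.append(f"{chrom}:{start}-{end}")
        chrom_len = chip.chrom_length(chrom)
        edges = _profile_edges_region(start, end, flank, body_bins, flank_bins)
        row = np.array(
            [_bin_intensity(chip, input_track, chrom, s, e, chrom_len, eps) for s, e in edges]
        )
        if strands is not None and strands[r] == "-":
            row = row[::-1]
        matrix[r] = row
    return MetaProfile(matrix, flank_bins=flank_bins, body_bins=body_bins, feature_ids=ids)


def tss_metaprofile(
    chip: SignalTrack,
    input_track: SignalTrack,
    tss_list,
    half_width: int = 5_000,
    bins: int = 100,
    eps: float = DENSITY_EPS,
) -> MetaProfile:
    """Fixed-width meta-profile centered on TSSs.

    ``tss_list`` is an iterable of (chrom, position, strand).  Minus-strand
    profiles are reversed so bin order is 5' to 3'.
    """
    tss_list = list(tss_list)
    if not tss_list:
        raise ValueError("empty TSS set")
    bw = 2 * half_width / bins
    matrix = np.full((len(tss_list), bins), np.nan)
    ids = []
    for r, (chrom, pos, strand) in enumerate(tss_list):
        chrom_len = chip.chrom_length(chrom)
        if not (0 <= pos < chrom_len):
            raise ValueError(f"TSS {chrom}:{pos} off chromosome")
        ids.append(f"{chrom}:{pos}({strand})")
        edges = [(pos - half_width + i * bw, pos - half_width + (i + 1) * bw) for i in range(bins)]
        row = np.array(
            [_bin_intensity(chip, input_track, chrom, s, e, chrom_len, eps) for s, e in edges]
        )
        if strand == "-":
            row = row[::-1]
        matrix[r] = row
    return MetaProfile(matrix, flank_bins=0, body_bins=bins, feature_ids=ids)


def compare_intensity(groups: dict[str, np.ndarray], equal_var: bool = True) -> pd.DataFrame:
    """Pairwise two-tailed Student t comparisons of per-feature intensities.

    Returns one row per class pair with t, p and significance stars.
    Classes with fewer than 2 members are skipped with a warning.
    """
    usable = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            warnings.warn(f"class {name!r} has < 2 members; skipped")
            continue
        usable[name] = vals
    rows = []
    names = list(usable)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = two_group_t(usable[a], usable[b], equal_var=equal_var)
            rows.append(
                {"class_a": a, "class_b": b, "mean_a": usable[a].mean(),
                 "mean_b": usable[b].mean(), "t": t, "p": p,
                 "stars": significance_stars(p)}
            )
    return pd.DataFrame(rows)
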