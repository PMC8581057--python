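"""Synthetic multi-omic experiment with planted ground truth.

Emulates the data the resistance scan consumes: six sample groups (donor
fibroblasts PFF; in-vivo two- and four-cell embryos IVO2c / IVO4c; cloned
four-cell embryos SCNT4c; and two treated cloned groups SCNT4c-KG /
SCNT4c-TDG) with negative-binomial gene, window-tile and repeat counts,
Poisson ChIP / input coverage enriched on resistant features, and
binomially sampled CpG methylation.  Every planted label is recorded in a
truth table so each analysis stage can be scored against what was planted.

Planted structure
-----------------
* genes: EGA-activated genes rise ``activation_fc``-fold at IVO4c; a
  configured fraction of them fails in SCNT4c (EGA-OFF).  Donor-expressed
  genes fall at EGA (PFF-OFF); a fraction stays on in SCNT4c (PFF-ON).
* regions: activation and silencing are planted as contiguous blocks of
  window tiles, aligned to the window step grid so that truth boundaries
  are well defined on the tiling.
* ChIP: the repressive mark is ``chip_enrich_fc``-fold enriched on
  resistant blocks and resistant-gene promoters; the matched input is flat.
* methylation: the donor genome is hypermethylated (``meth_high``) outside
  CpG islands; embryos demethylate globally to an intermediate level, with
  resistant features retaining ``meth_high`` and activated blocks plus CGIs
  dropping to ``meth_low``.  The TDG-treated group demethylates resistant
  features as well.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .chip import SignalTrack
from .genome import GenomeLayout, Window, make_windows
from .methylation import CpGCallSet
from .quantify import CountMatrix

GROUPS = ("PFF", "IVO2c", "IVO4c", "SCNT4c", "SCNT4c-KG", "SCNT4c-TDG")
TREATED_GROUPS = ("SCNT4c-KG", "SCNT4c-TDG")
METH_GROUPS = ("PFF", "SCNT4c", "SCNT4c-TDG")

# truth-table vocabulary (gene/region axis labels and repeat tiers)
T_EGA_FULLY_ON = "EGA_FULLY_ON"
T_EGA_OFF = "EGA_OFF"
T_PFF_FULLY_OFF = "PFF_FULLY_OFF"
T_PFF_ON = "PFF_ON"
T_NONE = "NONE"

_REPEAT_FAMILIES = (
    "LTR/ERV1", "LINE/L1", "SINE/PRE1", "satellite/SSRS1", "DNA/hAT",
)
#: planted IVO4c/IVO2c fold changes for repeat tiers >1, >2, >5
_REPEAT_TIER_FCS = ((1.5, "GT1"), (3.0, "GT2"), (8.0, "GT5"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    The negative binomial is parameterized as ``var = mu + dispersion *
    mu**2``.  Fractions convert to feature counts by ``floor(frac * n)``
    and labels are assigned through a seed-deterministic shuffle, so the
    planted label counts are exact.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 1_000
    n_repeats: int = 300
    replicates_per_group: int = 2
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    frac_ega_on: float = 0.2
    frac_ega_off_given_on: float = 0.4
    frac_pff_off: float = 0.2
    frac_pff_on_given_off: float = 0.3
    activation_fc: float = 10.0
    chip_enrich_fc: float = 4.0
    meth_high: float = 0.8
    meth_low: float = 0.2
    restore_frac: float = 0.6
    # ---- plumbing defaults (genome geometry and assay depths) ----
    meth_mid: float = 0.5          # embryo-wide post-EGA background level
    window_size: int = 50_000
    window_step: int = 20_000
    tile_size: int = 10_000        # gcd of window size and step
    tile_mean: float = 20.0        # expected reads per tile per replicate
    n_ega_on_blocks: int = 2
    n_ega_off_blocks: int = 3
    n_pff_off_blocks: int = 2
    n_pff_on_blocks: int = 2
    block_min: int = 100_000
    block_max: int = 200_000
    chip_bin: int = 200
    chip_rate: float = 5.0         # expected input reads per bin
    cpg_spacing: int = 200
    cpg_coverage: float = 10.0
    cgi_frac: float = 0.5          # fraction of gene promoters carrying a CGI
    cgi_half_width: int = 1_000
    promoter_half_width: int = 5_000

    def __post_init__(self) -> None:
        fracs = (
            self.frac_ega_on, self.frac_ega_off_given_on, self.frac_pff_off,
            self.frac_pff_on_given_off, self.restore_frac, self.cgi_frac,
            self.meth_high, self.meth_low, self.meth_mid,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions and methylation levels must lie in [0, 1]")
        if self.replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if self.chrom_length < self.window_size:
            raise ValueError("chrom_length must be at least the window size")
        if min(self.baseline_mean, self.dispersion, self.tile_mean, self.chip_rate) <= 0:
            raise ValueError("means and dispersion must be > 0")
        if self.frac_ega_on + self.frac_pff_off > 1.0:
            raise ValueError("EGA and PFF gene fractions overlap")
        if self.window_size % self.tile_size or self.window_step % self.tile_size:
            raise ValueError("tile_size must divide window size and step")


@dataclass
class SimulatedExperiment:
    """Everything one simulation run produces, plus internal truth."""

    config: SimulationConfig
    layout: GenomeLayout
    gene_counts: CountMatrix
    window_counts: CountMatrix
    windows: list[Window]
    repeat_counts: CountMatrix
    chip_tracks: dict[str, SignalTrack]
    cpg_calls: dict[str, CpGCallSet]
    genes: pd.DataFrame
    repeats: pd.DataFrame
    cgi: pd.DataFrame
    truth: pd.DataFrame
    cpg_coverage: dict[str, np.ndarray] = field(default_factory=dict)


def _sample_ids(reps: int) -> list[str]:
    return [f"{g}_r{r + 1}" for g in GROUPS for r in range(reps)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _count_matrix(rng, means: dict[str, np.ndarray], index: pd.Index, cfg: SimulationConfig) -> CountMatrix:
    """Draw NB counts for every group/replicate from per-group mean vectors."""
    reps = cfg.replicates_per_group
    cols = {}
    for g in GROUPS:
        for r in range(reps):
            cols[f"{g}_r{r + 1}"] = _nb_draw(rng, means[g], cfg.dispersion)
    counts = pd.DataFrame(cols, index=index)
    lib = counts.sum(axis=0).astype(float).clip(lower=1.0)
    samples = pd.DataFrame(
        {
            "group": [g for g in GROUPS for _ in range(reps)],
            "replicate": [r + 1 for _ in GROUPS for r in range(reps)],
            "library_size": lib.to_numpy(),
        },
        index=pd.Index(_sample_ids(reps), name="sample_id"),
    )
    return CountMatrix(counts, samples)


def _place_genes(cfg: SimulationConfig, layout: GenomeLayout) -> pd.DataFrame:
    margin = max(20_000, cfg.promoter_half_width + 10_000)
    per_chrom = [cfg.n_genes // cfg.n_chroms + (1 if c < cfg.n_genes % cfg.n_chroms else 0)
                 for c in range(cfg.n_chroms)]
    rows = []
    gid = 0
    for c, (chrom, length) in enumerate(layout.iter_chroms()):
        n_c = per_chrom[c]
        if n_c == 0:
            continue
        usable = length - 2 * margin
        spacing = usable // n_c
        gene_len_cycle = (2_000, 3_000, 4_000, 5_000)
        if spacing < max(gene_len_cycle) + 1:
            raise ValueError("chromosome too short to host the requested genes")
        for j in range(n_c):
            start = margin + j * spacing
            glen = gene_len_cycle[gid % len(gene_len_cycle)]
            strand = "+" if gid % 2 == 0 else "-"
            end = start + glen
            rows.append(
                {"gene_id": f"gene{gid:05d}", "chrom": chrom, "start": start,
                 "end": end, "strand": strand, "length": glen,
                 "tss": start if strand == "+" else end}
            )
            gid += 1
    return pd.DataFrame(rows).set_index("gene_id")


def _place_repeats(cfg: SimulationConfig, layout: GenomeLayout) -> pd.DataFrame:
    margin = 15_000
    per_chrom = [cfg.n_repeats // cfg.n_chroms + (1 if c < cfg.n_repeats % cfg.n_chroms else 0)
                 for c in range(cfg.n_chroms)]
    rows = []
    rid = 0
    for c, (chrom, length) in enumerate(layout.iter_chroms()):
        n_c = per_chrom[c]
        if n_c == 0:
            continue
        spacing = (length - 2 * margin) // n_c
        if spacing < 1_000:
            raise ValueError("chromosome too short to host the requested repeats")
        for j in range(n_c):
            start = margin + j * spacing + 500  # offset from gene grid
            rows.append(
                {"repeat_id": f"rep{rid:05d}", "chrom": chrom, "start": start,
                 "end": start + 500, "strand": "+",
                 "family": _REPEAT_FAMILIES[rid % len(_REPEAT_FAMILIES)]}
            )
            rid += 1
    return pd.DataFrame(rows).set_index("repeat_id")


def _place_blocks(cfg: SimulationConfig, layout: GenomeLayout, rng) -> pd.DataFrame:
    """Plant labeled blocks, starts on the window-step grid.

    Block starts sit on the step grid and lengths are ``step/2`` off the
    grid modulo step, which keeps every partial window's planted fold
    change far from the classification boundary.
    """
    step = cfg.window_step
    kinds = (
        [T_EGA_FULLY_ON] * cfg.n_ega_on_blocks
        + [T_EGA_OFF] * cfg.n_ega_off_blocks
        + [T_PFF_FULLY_OFF] * cfg.n_pff_off_blocks
        + [T_PFF_ON] * cfg.n_pff_on_blocks
    )
    # candidate lengths: in [block_min, block_max], congruent to step/2 mod step
    half = step // 2
    lengths = [L for L in range(cfg.block_min, cfg.block_max + 1, half)
               if L % step == half]
    if not lengths:
        raise ValueError("no admissible block length in [block_min, block_max]")
    per_chrom: dict[str, list[str]] = {c: [] for c in layout.chroms}
    for i, kind in enumerate(kinds):
        per_chrom[layout.chroms[i % cfg.n_chroms]].append(kind)
    rows = []
    bid = 0
    for chrom, chrom_kinds in per_chrom.items():
        k = len(chrom_kinds)
        if k == 0:
            continue
        length = layout.length_of(chrom)
        for j, kind in enumerate(chrom_kinds):
            center = (j + 1) * length // (k + 1)
            start = (center // step) * step
            blen = int(rng.choice(lengths))
            end = start + blen
            if start < 300_000 or end > length - 300_000:
                raise ValueError("chromosome too short to host the requested blocks")
            rows.append({"block_id": f"block{bid:02d}", "chrom": chrom,
                         "start": start, "end": end, "kind": kind})
            bid += 1
    df = pd.DataFrame(rows)
    if len(df):
        prev_end = {}
        for row in df.sort_values(["chrom", "start"]).itertuples():
            if row.chrom in prev_end and row.start - prev_end[row.chrom] < 2 * cfg.window_size:
                raise ValueError("planted blocks too close; enlarge the chromosome")
            prev_end[row.chrom] = row.end
    return df.set_index("block_id") if len(df) else df


def _gene_truth(cfg: SimulationConfig, genes: pd.DataFrame, rng) -> pd.DataFrame:
    n = len(genes)
    n_ega = int(np.floor(cfg.frac_ega_on * n))
    n_ega_off = int(np.floor(cfg.frac_ega_off_given_on * n_ega))
    n_pff = int(np.floor(cfg.frac_pff_off * n))
    n_pff_on = int(np.floor(cfg.frac_pff_on_given_off * n_pff))
    perm = rng.permutation(n)
    label = np.full(n, T_NONE, dtype=object)
    label[perm[:n_ega_off]] = T_EGA_OFF
    label[perm[n_ega_off:n_ega]] = T_EGA_FULLY_ON
    label[perm[n_ega:n_ega + n_pff_on]] = T_PFF_ON
    label[perm[n_ega + n_pff_on:n_ega + n_pff]] = T_PFF_FULLY_OFF
    restored = np.zeros(n, dtype=bool)
    off_idx = perm[:n_ega_off]
    restored[off_idx[: int(np.floor(cfg.restore_frac * n_ega_off))]] = True
    on_idx = perm[n_ega:n_ega + n_pff_on]
    restored[on_idx[: int(np.floor(cfg.restore_frac * n_pff_on))]] = True
    return pd.DataFrame({"planted_label": label, "planted_restored": restored},
                        index=genes.index)


def _gene_means(cfg: SimulationConfig, truth: pd.DataFrame) -> dict[str, np.ndarray]:
    base = cfg.baseline_mean
    hi = cfg.activation_fc * base
    n = len(truth)
    label = truth["planted_label"].to_numpy()
    restored = truth["planted_restored"].to_numpy()
    means = {g: np.full(n, base) for g in GROUPS}
    is_ega = (label == T_EGA_FULLY_ON) | (label == T_EGA_OFF)
    means["IVO4c"][is_ega] = hi
    means["SCNT4c"][label == T_EGA_FULLY_ON] = hi
    is_pff = (label == T_PFF_FULLY_OFF) | (label == T_PFF_ON)
    means["PFF"][is_pff] = hi
    means["SCNT4c"][label == T_PFF_ON] = hi
    for g in TREATED_GROUPS:
        means[g] = means["SCNT4c"].copy()
        means[g][(label == T_EGA_OFF) & restored] = hi   # reactivated to IVO4c level
        means[g][(label == T_PFF_ON) & restored] = base  # silenced to IVO4c level
    return means


def _repeat_truth(cfg: SimulationConfig, repeats: pd.DataFrame, rng) -> pd.DataFrame:
    n = len(repeats)
    n_on = int(np.floor(cfg.frac_ega_on * n))
    perm = rng.permutation(n)
    label = np.full(n, T_NONE, dtype=object)
    planted_fc = np.ones(n)
    for j in range(n_on):
        fc, tier = _REPEAT_TIER_FCS[j % len(_REPEAT_TIER_FCS)]
        label[perm[j]] = tier
        planted_fc[perm[j]] = fc
    restored = np.zeros(n, dtype=bool)
    restored[perm[: int(np.floor(cfg.restore_frac * n_on))]] = True
    return pd.DataFrame(
        {"planted_label": label, "planted_fc": planted_fc, "planted_restored": restored},
        index=repeats.index,
    )


def _repeat_means(cfg: SimulationConfig, truth: pd.DataFrame) -> dict[str, np.ndarray]:
    base = cfg.baseline_mean
    n = len(truth)
    fc = truth["planted_fc"].to_numpy()
    restored = truth["planted_restored"].to_numpy()
    on = truth["planted_label"].to_numpy() != T_NONE
    means = {g: np.full(n, base) for g in GROUPS}
    means["IVO4c"] = np.where(on, fc * base, base)
    for g in TREATED_GROUPS:
        means[g] = np.where(on & restored, fc * base, base)
    return means


def _tile_means(cfg: SimulationConfig, layout: GenomeLayout, blocks: pd.DataFrame):
    """Per-tile expected counts per group, and the tile index frame."""
    tiles = []
    for chrom, length in layout.iter_chroms():
        for start in range(0, length - cfg.tile_size + 1, cfg.tile_size):
            tiles.append((chrom, start, start + cfg.tile_size))
    tile_df = pd.DataFrame(tiles, columns=["chrom", "start", "end"])
    n = len(tile_df)
    base = cfg.tile_mean
    hi = cfg.activation_fc * base
    means = {g: np.full(n, base) for g in GROUPS}
    restored_blocks = _restored_block_ids(cfg, blocks)
    for block in blocks.itertuples():
        sel = (
            (tile_df["chrom"] == block.chrom)
            & (tile_df["start"] >= block.start)
            & (tile_df["end"] <= block.end)
        ).to_numpy()
        restored = block.Index in restored_blocks
        if block.kind == T_EGA_FULLY_ON:
            for g in ("IVO4c", "SCNT4c", "SCNT4c-KG", "SCNT4c-TDG"):
                means[g][sel] = hi
        elif block.kind == T_EGA_OFF:
            means["IVO4c"][sel] = hi
            if restored:
                for g in TREATED_GROUPS:
                    means[g][sel] = hi
        elif block.kind == T_PFF_FULLY_OFF:
            means["PFF"][sel] = hi
        elif block.kind == T_PFF_ON:
            means["PFF"][sel] = hi
            means["SCNT4c"][sel] = hi
            if not restored:
                for g in TREATED_GROUPS:
                    means[g][sel] = hi
    return tile_df, means


def _restored_block_ids(cfg: SimulationConfig, blocks: pd.DataFrame) -> set:
    out = set()
    if not len(blocks):
        return out
    for kind in (T_EGA_OFF, T_PFF_ON):
        ids = list(blocks.index[blocks["kind"] == kind])
        out.update(ids[: int(np.floor(cfg.restore_frac * len(ids)))])
    return out


def _window_counts_from_tiles(
    cfg: SimulationConfig, layout: GenomeLayout, tile_df: pd.DataFrame,
    tile_counts: pd.DataFrame, windows: list[Window],
) -> pd.DataFrame:
    """Sum tile counts into sliding windows (windows are whole tiles)."""
    per_chrom_csum = {}
    for chrom in layout.chroms:
        sub = tile_counts[(tile_df["chrom"] == chrom).to_numpy()]
        csum = np.zeros((len(sub) + 1, tile_counts.shape[1]), dtype=np.int64)
        np.cumsum(sub.to_numpy(), axis=0, out=csum[1:])
        per_chrom_csum[chrom] = csum
    rows = np.zeros((len(windows), tile_counts.shape[1]), dtype=np.int64)
    ts = cfg.tile_size
    for i, w in enumerate(windows):
        csum = per_chrom_csum[w.chrom]
        rows[i] = csum[w.end // ts] - csum[w.start // ts]
    index = pd.Index([f"{w.chrom}:{w.start}-{w.end}" for w in windows], name="window_id")
    return pd.DataFrame(rows, index=index, columns=tile_counts.columns)


def _resistant_intervals(blocks: pd.DataFrame, genes: pd.DataFrame,
                         gene_truth: pd.DataFrame, cfg: SimulationConfig):
    """Intervals carrying repressive-mark enrichment and retained methylation."""
    out = []
    for block in blocks.itertuples():
        if block.kind in (T_EGA_OFF, T_PFF_ON):
            out.append((block.chrom, block.start, block.end))
    resistant = gene_truth["planted_label"].isin([T_EGA_OFF, T_PFF_ON])
    for gid in gene_truth.index[resistant]:
        g = genes.loc[gid]
        out.append((g["chrom"], max(0, g["tss"] - cfg.promoter_half_width),
                    g["tss"] + cfg.promoter_half_width))
    return out


def _chip_tracks(cfg, layout, resistant, rng) -> dict[str, SignalTrack]:
    tracks: dict[str, SignalTrack] = {}
    for group in ("PFF", "SCNT4c"):
        rate = {
            c: np.full(-(-length // cfg.chip_bin), cfg.chip_rate)
            for c, length in layout.iter_chroms()
        }
        for chrom, start, end in resistant:
            b0, b1 = start // cfg.chip_bin, -(-end // cfg.chip_bin)
            rate[chrom][b0:b1] = cfg.chip_rate * cfg.chip_enrich_fc
        for role, mark, rmap in (
            ("chip", "H3K9me3", rate),
            ("input", "input", {c: np.full_like(r, cfg.chip_rate) for c, r in rate.items()}),
        ):
            bins = {c: rng.poisson(r).astype(float) for c, r in rmap.items()}
            lib = float(sum(b.sum() for b in bins.values()))
            key = f"{mark}_{group}" if role == "chip" else f"input_{group}"
            tracks[key] = SignalTrack(bins=bins, bin_width=cfg.chip_bin,
                                      library_size=max(lib, 1.0), role=role, mark=mark)
    return tracks


def simulate_cpg_calls(positions_by_chrom, levels_by_chrom, coverage_rate, rng) -> tuple[CpGCallSet, np.ndarray]:
    """Draw a CpG call set from per-site levels.

    Coverage is Poisson(``coverage_rate``) per CpG and the methylated count
    is Binomial(coverage, level).  Returns the call set and the drawn
    coverage array (all chroms concatenated in layout order).
    """
    frames = []
    coverages = []
    for chrom, positions in positions_by_chrom.items():
        levels = np.asarray(levels_by_chrom[chrom], dtype=float)
        cov = rng.poisson(coverage_rate, size=len(positions))
        meth = rng.binomial(cov, levels)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": positions, "strand": "+",
            "meth": meth, "unmeth": cov - meth,
        }))
        coverages.append(cov)
    calls = CpGCallSet(pd.concat(frames, ignore_index=True))
    return calls, np.concatenate(coverages)


def _cpg_levels(cfg, layout, blocks, genes, gene_truth, cgi, group: str):
    """Planted methylation level per CpG site for one sample group."""
    positions = {c: np.arange(cfg.cpg_spacing // 2, length, cfg.cpg_spacing)
                 for c, length in layout.iter_chroms()}
    base = cfg.meth_high if group == "PFF" else cfg.meth_mid
    levels = {c: np.full(len(p), base) for c, p in positions.items()}

    def paint(chrom, start, end, value):
        p = positions[chrom]
        levels[chrom][(p >= start) & (p < end)] = value

    embryo = group != "PFF"
    for block in blocks.itertuples():
        if block.kind == T_EGA_FULLY_ON and embryo:
            paint(block.chrom, block.start, block.end, cfg.meth_low)
        elif block.kind in (T_EGA_OFF, T_PFF_ON):
            value = cfg.meth_low if group == "SCNT4c-TDG" else cfg.meth_high
            paint(block.chrom, block.start, block.end, value)
    resistant = gene_truth["planted_label"].isin([T_EGA_OFF, T_PFF_ON])
    for gid in gene_truth.index[resistant]:
        g = genes.loc[gid]
        value = cfg.meth_low if group == "SCNT4c-TDG" else cfg.meth_high
        paint(g["chrom"], max(0, g["tss"] - cfg.promoter_half_width),
              g["tss"] + cfg.promoter_half_width, value)
    for row in cgi.itertuples(index=False):
        paint(row.chrom, row.start, row.end, cfg.meth_low)  # CGIs stay hypomethylated
    return positions, levels


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the full generator; one rng drives everything for bit-for-bit determinism."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = GenomeLayout({f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)})

    genes = _place_genes(cfg, layout)
    repeats = _place_repeats(cfg, layout)
    blocks = _place_blocks(cfg, layout, rng)
    gene_truth = _gene_truth(cfg, genes, rng)
    repeat_truth = _repeat_truth(cfg, repeats, rng)

    gene_counts = _count_matrix(rng, _gene_means(cfg, gene_truth), genes.index, cfg)
    repeat_counts = _count_matrix(rng, _repeat_means(cfg, repeat_truth), repeats.index, cfg)

    tile_df, tile_means = _tile_means(cfg, layout, blocks)
    tile_counts = _count_matrix(rng, tile_means, pd.RangeIndex(len(tile_df)), cfg)
    windows = make_windows(layout, cfg.window_size, cfg.window_step)
    window_values = _window_counts_from_tiles(cfg, layout, tile_df, tile_counts.counts, windows)
    window_counts = CountMatrix(window_values, tile_counts.samples)

    resistant = _resistant_intervals(blocks, genes, gene_truth, cfg)
    chip_tracks = _chip_tracks(cfg, layout, resistant, rng)

    # CGIs at a deterministic-shuffled subset of promoters
    n_cgi = int(np.floor(cfg.cgi_frac * len(genes)))
    cgi_gene_ids = genes.index[np.sort(rng.permutation(len(genes))[:n_cgi])]
    cgi = pd.DataFrame(
        {
            "chrom": genes.loc[cgi_gene_ids, "chrom"].to_numpy(),
            "start": (genes.loc[cgi_gene_ids, "tss"] - cfg.cgi_half_width).clip(lower=0).to_numpy(),
            "end": (genes.loc[cgi_gene_ids, "tss"] + cfg.cgi_half_width).to_numpy(),
        }
    )

    cpg_calls: dict[str, CpGCallSet] = {}
    cpg_coverage: dict[str, np.ndarray] = {}
    for group in METH_GROUPS:
        positions, levels = _cpg_levels(cfg, layout, blocks, genes, gene_truth, cgi, group)
        cpg_calls[group], cpg_coverage[group] = simulate_cpg_calls(
            positions, levels, cfg.cpg_coverage, rng
        )

    truth_frames = [
        pd.DataFrame(
            {"feature_id": gene_truth.index, "feature_kind": "gene",
             "planted_label": gene_truth["planted_label"].to_numpy(),
             "planted_restored": gene_truth["planted_restored"].to_numpy()}
        ),
        pd.DataFrame(
            {"feature_id": [f"{b.chrom}:{b.start}-{b.end}" for b in blocks.itertuples()],
             "feature_kind": "window-region",
             "planted_label": [b.kind for b in blocks.itertuples()],
             "planted_restored": [b.Index in _restored_block_ids(cfg, blocks)
                                  for b in blocks.itertuples()]}
        ),
        pd.DataFrame(
            {"feature_id": repeat_truth.index, "feature_kind": "repeat",
             "planted_label": repeat_truth["planted_label"].to_numpy(),
             "planted_restored": repeat_truth["planted_restored"].to_numpy()}
        ),
    ]
    truth = pd.concat(truth_frames, ignore_index=True)

    return SimulatedExperiment(
        config=cfg, layout=layout, gene_counts=gene_counts,
        window_counts=window_counts, windows=windows, repeat_counts=repeat_counts,
        chip_tracks=chip_tracks, cpg_calls=cpg_calls, genes=genes,
        repeats=repeats, cgi=cgi, truth=truth, cpg_coverage=cpg_coverage,
    )


def config_to_yaml(cfg: SimulationConfig) -> str:
    import yaml

    return yaml.safe_dump(asdict(cfg), sort_keys=True)


def config_from_yaml(text: str) -> SimulationConfig:
    import yaml

    data = yaml.safe_load(text) or {}
    return SimulationConfig(**data)
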