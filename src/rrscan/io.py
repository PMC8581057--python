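"""Readers and writers for the plain-text formats the pipeline speaks.

Counts travel as TSV (feature id column + one column per sample, with a
sidecar sample-metadata TSV), annotations as BED (0-based half-open),
signal as bedGraph with a library-size sidecar, CpG calls as a 5-column
cytosine report (1-based).  All writers are deterministic: fixed column
order, fixed float formatting.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .chip import SignalTrack
from .genome import GenomeLayout, write_chrom_sizes
from .methylation import write_cpg_calls
from .quantify import CountMatrix

FLOAT_FMT = "%.10g"


def write_count_matrix(matrix: CountMatrix, counts_path, samples_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.samples.to_csv(samples_path, sep="\t", float_format=FLOAT_FMT)


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts, samples)


def write_bed6(df: pd.DataFrame, path, name_col: str, score=0) -> None:
    """BED6 from a frame with chrom/start/end/strand; ``name_col`` may be the index."""
    with open(path, "w") as fh:
        for fid, row in df.iterrows():
            name = fid if name_col == "index" else row[name_col]
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t{score}\t{row['strand']}\n"
            )


def read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, score, strand = line.rstrip("\n").split("\t")[:6]
            rows.append((c, int(s), int(e), name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_bed3(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_bed3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e = line.rstrip("\n").split("\t")[:3]
            rows.append((c, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bedgraph(track: SignalTrack, path) -> None:
    """Run-length-compressed bedGraph (0-based half-open); zero runs skipped."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, arr in track.bins.items():
            n = len(arr)
            i = 0
            while i < n:
                j = i
                while j + 1 < n and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0:
                    fh.write(f"{chrom}\t{i * bw}\t{(j + 1) * bw}\t{FLOAT_FMT % arr[i]}\n")
                i = j + 1


def read_bedgraph(
    path, layout: GenomeLayout, bin_width: int, library_size: float,
    role: str = "chip", mark: str = "",
) -> SignalTrack:
    track = SignalTrack.zeros(layout, bin_width, role=role, mark=mark)
    track.library_size = library_size
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.rstrip("\n").split("\t")[:4]
            s, e, v = int(s), int(e), float(v)
            if s % bin_width or (e % bin_width and e != layout.length_of(chrom)):
                raise ValueError(f"{path}:{i}: interval not aligned to {bin_width}-bp bins")
            track.bins[chrom][s // bin_width: -(-e // bin_width)] = v
    return track


def write_track_sidecar(tracks: dict[str, SignalTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("track\tmark\trole\tbin_width\tlibrary_size\n")
        for name, t in tracks.items():
            fh.write(f"{name}\t{t.mark}\t{t.role}\t{t.bin_width}\t{FLOAT_FMT % t.library_size}\n")


def read_track_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fixture(dataset, out_dir) -> list[str]:
    """Write a simulated experiment as a self-contained plain-text file set.

    Reading the files back (:func:`read_fixture`) reproduces the in-memory
    objects exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def path(name):
        written.append(name)
        return os.path.join(out_dir, name)

    write_chrom_sizes(dataset.layout, path("chrom.sizes"))
    write_count_matrix(dataset.gene_counts, path("genes.counts.tsv"), path("genes.samples.tsv"))
    write_count_matrix(dataset.window_counts, path("windows.counts.tsv"), path("windows.samples.tsv"))
    write_count_matrix(dataset.repeat_counts, path("repeats.counts.tsv"), path("repeats.samples.tsv"))
    write_bed6(dataset.genes, path("genes.bed"), "index")
    rep = dataset.repeats.copy()
    rep["name"] = [f"{rid}|{fam}" for rid, fam in rep["family"].items()]
    write_bed6(rep, path("repeats.bed"), "name")
    write_bed3(dataset.cgi, path("cgi.bed"))
    dataset.truth.to_csv(path("truth.tsv"), sep="\t", index=False)
    for name, track in dataset.chip_tracks.items():
        write_bedgraph(track, path(f"{name}.bedGraph"))
    write_track_sidecar(dataset.chip_tracks, path("tracks.tsv"))
    for group, calls in dataset.cpg_calls.items():
        write_cpg_calls(calls, path(f"cpg.{group}.tsv"))
    from .simulate import config_to_yaml

    with open(path("config.yaml"), "w") as fh:
        fh.write(config_to_yaml(dataset.config))
    return written


def read_fixture(out_dir):
    """Reload a fixture directory written by :func:`write_fixture`."""
    from .genome import read_chrom_sizes
    from .methylation import read_cpg_calls
    from .simulate import config_from_yaml

    def path(name):
        return os.path.join(out_dir, name)

    with open(path("config.yaml")) as fh:
        config = config_from_yaml(fh.read())
    layout = read_chrom_sizes(path("chrom.sizes"))
    sidecar = read_track_sidecar(path("tracks.tsv"))
    tracks = {
        name: read_bedgraph(
            path(f"{name}.bedGraph"), layout, int(row["bin_width"]),
            float(row["library_size"]), role=row["role"],
            mark="" if pd.isna(row["mark"]) else row["mark"],
        )
        for name, row in sidecar.iterrows()
    }
    cpg = {}
    for name in sorted(os.listdir(out_dir)):
        if name.startswith("cpg.") and name.endswith(".tsv"):
            cpg[name[4:-4]] = read_cpg_calls(path(name))
    return {
        "config": config,
        "layout": layout,
        "gene_counts": read_count_matrix(path("genes.counts.tsv"), path("genes.samples.tsv")),
        "window_counts": read_count_matrix(path("windows.counts.tsv"), path("windows.samples.tsv")),
        "repeat_counts": read_count_matrix(path("repeats.counts.tsv"), path("repeats.samples.tsv")),
        "genes": read_bed6(path("genes.bed")),
        "repeats": read_bed6(path("repeats.bed")),
        "cgi": read_bed3(path("cgi.bed")),
        "truth": pd.read_csv(path("truth.tsv"), sep="\t"),
        "chip_tracks": tracks,
        "cpg_calls": cpg,
    }


def write_classified_bed(features, path) -> None:
    """Classified features as BED6+ (score = -log10 p, then label and FCs)."""
    with open(path, "w") as fh:
        for f in features:
            if f.chrom is None:
                continue
            score = -np.log10(f.p) if f.p and f.p > 0 else 320.0
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t{FLOAT_FMT % score}\t.\t"
                f"{f.label}\t{FLOAT_FMT % f.fc_primary}\t{FLOAT_FMT % f.fc_secondary}\n"
            )
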