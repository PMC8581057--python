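"""End-to-end run: simulate, classify, score restoration, profile marks and
methylation, and write every result as deterministic plain text."""
from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import classify as cls
from . import io as rio
from .chip import interval_intensities, region_metaprofile
from .differential import gene_diff_table
from .methylation import meth_level
from .quantify import fpkm_table, mor_table, vst
from .simulate import (
    T_EGA_FULLY_ON,
    T_EGA_OFF,
    T_PFF_FULLY_OFF,
    T_PFF_ON,
    SimulationConfig,
    simulate_experiment,
)

#: truth-table label -> (axis, classify label)
TRUTH_TO_CLASS = {
    T_EGA_FULLY_ON: (cls.EGA_AXIS, cls.FULLY_ON),
    T_EGA_OFF: (cls.EGA_AXIS, cls.OFF),
    T_PFF_FULLY_OFF: (cls.PFF_AXIS, cls.FULLY_OFF),
    T_PFF_ON: (cls.PFF_AXIS, cls.ON),
}


def classify_gene_axes(dataset, thr: cls.ThresholdConfig | None = None):
    """Normalized tables, both gene-axis classifications, and the diff tables.

    FPKM supplies the expression floor; fold changes are computed on
    median-of-ratios-normalized counts, which are robust to the
    composition shift of the transcriptional burst at EGA.
    """
    thr = thr or cls.ThresholdConfig()
    expr = fpkm_table(dataset.gene_counts, dataset.genes["length"])
    norm = mor_table(dataset.gene_counts)
    diff_ega = gene_diff_table(dataset.gene_counts, "IVO4c", "IVO2c")
    diff_pff = gene_diff_table(dataset.gene_counts, "PFF", "IVO4c")
    ega = cls.classify_ega_genes(expr, diff_ega, thr, norm=norm)
    pff = cls.classify_pff_genes(expr, diff_pff, thr, norm=norm)
    return norm, ega, pff


def label_accuracy(features, truth: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Sensitivity / precision per planted class on one axis."""
    truth = truth[truth["feature_kind"] == "gene"].set_index("feature_id")
    by_id = {f.feature_id: f for f in features}
    rows = []
    for t_label, (t_axis, c_label) in TRUTH_TO_CLASS.items():
        if t_axis != axis:
            continue
        planted = set(truth.index[truth["planted_label"] == t_label])
        called = {fid for fid, f in by_id.items() if f.label == c_label}
        tp = len(planted & called)
        rows.append(
            {
                "class": t_label,
                "n_planted": len(planted),
                "n_called": len(called),
                "sensitivity": tp / len(planted) if planted else float("nan"),
                "precision": tp / len(called) if called else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: SimulationConfig, out_dir, thr: cls.ThresholdConfig | None = None) -> dict:
    """Simulate and analyze one experiment; write all outputs under ``out_dir``.

    Returns the summary dictionary that is also written as ``summary.json``.
    """
    thr = thr or cls.ThresholdConfig()
    os.makedirs(out_dir, exist_ok=True)
    dataset = simulate_experiment(config)
    rio.write_fixture(dataset, os.path.join(out_dir, "fixture"))

    # genes
    norm, ega, pff = classify_gene_axes(dataset, thr)
    restored = {}
    for treated in ("SCNT4c-KG", "SCNT4c-TDG"):
        for key, frac in cls.assess_restoration(ega + pff, norm, treated, thr=thr).items():
            restored[f"gene_{key}_{treated}"] = frac
    gene_frame = cls.classified_to_frame(ega + pff)
    gene_frame.to_csv(os.path.join(out_dir, "genes.classified.tsv"), sep="\t",
                      index=False, float_format=rio.FLOAT_FMT)

    # regions
    regions_all = []
    region_expr = {}
    for axis in (cls.EGA_AXIS, cls.PFF_AXIS):
        regions, region_counts = cls.classify_regions(
            dataset.window_counts, dataset.windows, thr, axis=axis
        )
        regions_all.extend(regions)
        if len(region_counts.counts):
            from .quantify import rpm_table

            region_expr[axis] = (regions, rpm_table(region_counts))
            for treated in ("SCNT4c-KG", "SCNT4c-TDG"):
                for key, frac in cls.assess_restoration(
                    regions, region_expr[axis][1], treated, thr=thr
                ).items():
                    restored[f"region_{key}_{treated}"] = frac
        rio.write_classified_bed(
            regions, os.path.join(out_dir, f"regions.{axis}.bed")
        )

    # repeats
    repeat_vst = vst(dataset.repeat_counts)
    repeats, repeat_summary = cls.classify_repeats(repeat_vst, dataset.repeats["family"], thr)
    cls.classified_to_frame(repeats).to_csv(
        os.path.join(out_dir, "repeats.classified.tsv"), sep="\t",
        index=False, float_format=rio.FLOAT_FMT,
    )

    # repressive-mark profile over resistant vs activated regions
    chip_summary = {}
    resistant_regions = [
        (f.chrom, f.start, f.end) for f in regions_all if f.resistant
    ]
    if resistant_regions:
        chip = dataset.chip_tracks["H3K9me3_SCNT4c"]
        inp = dataset.chip_tracks["input_SCNT4c"]
        prof = region_metaprofile(chip, inp, resistant_regions)
        body = float(np.nanmean(prof.mean[prof.body_slice()]))
        flank = float(np.nanmean(prof.mean[prof.flank_mask()]))
        chip_summary = {
            "resistant_body_intensity": body,
            "resistant_flank_intensity": flank,
            "body_minus_flank": body - flank,
            "mean_region_intensity": float(
                np.mean(interval_intensities(chip, inp, resistant_regions))
            ),
        }
        np.savetxt(
            os.path.join(out_dir, "chip.profile.resistant.tsv"),
            prof.mean[None, :], delimiter="\t", fmt=rio.FLOAT_FMT,
        )

    # methylation of resistant regions per group
    meth_summary = {}
    if resistant_regions:
        for group, calls in dataset.cpg_calls.items():
            levels = [
                lv.level for lv in meth_level(calls, resistant_regions) if lv.defined
            ]
            if levels:
                meth_summary[f"resistant_region_meth_{group}"] = float(np.mean(levels))

    summary = {
        "config_seed": config.seed,
        "n_ega_class_genes": int(sum(f.label != cls.NONE for f in ega)),
        "n_ega_off_genes": int(sum(f.label == cls.OFF for f in ega)),
        "n_pff_class_genes": int(sum(f.label != cls.NONE for f in pff)),
        "n_pff_on_genes": int(sum(f.label == cls.ON for f in pff)),
        "n_regions": len(regions_all),
        "n_resistant_regions": len(resistant_regions),
        "n_ega_on_repeats": int(sum(r.label != cls.NONE for r in repeats)),
        "repeat_class_composition": {k: int(v) for k, v in sorted(repeat_summary.items())},
        "restored_fractions": {k: restored[k] for k in sorted(restored)},
        "chip": chip_summary,
        "methylation": {k: meth_summary[k] for k in sorted(meth_summary)},
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
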