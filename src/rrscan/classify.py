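"""Threshold taxonomy for reprogramming-resistant features.

Genes and genomic regions are screened on a primary contrast (activation at
embryonic genome activation, IVO4c vs IVO2c; or donor-cell silencing, PFF vs
IVO4c) and then sub-grouped by how far the cloned embryo (SCNT4c) restores
them.  EGA-axis subgroups are FULLY_ON / PARTIALLY_ON / OFF; PFF-axis
subgroups are FULLY_OFF / PARTIALLY_OFF / ON.  EGA-OFF and PFF-ON features
together form the reprogramming-resistant set.  Boundary semantics follow
the published interval conventions exactly: EGA fully FC <= 2, partially
2 < FC <= 5, OFF FC > 5; PFF fully FC >= 5, partially 2 <= FC < 5, ON
FC < 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import (
    DEFAULT_PSEUDOCOUNT,
    fisher_window_test,
    fold_change,
    window_diff_table,
)
from .genome import Window
from .quantify import CountMatrix, ExpressionTable, delog_vst

# taxonomy vocabulary
EGA_AXIS = "EGA"
PFF_AXIS = "PFF"
FULLY_ON = "FULLY_ON"
PARTIALLY_ON = "PARTIALLY_ON"
OFF = "OFF"
FULLY_OFF = "FULLY_OFF"
PARTIALLY_OFF = "PARTIALLY_OFF"
ON = "ON"
NONE = "NONE"

EGA_LABELS = (FULLY_ON, PARTIALLY_ON, OFF)
PFF_LABELS = (FULLY_OFF, PARTIALLY_OFF, ON)

#: sample-group names used throughout; data with other names can remap
GROUPS = ("PFF", "IVO2c", "IVO4c", "SCNT4c", "SCNT4c-KG", "SCNT4c-TDG")


@dataclass
class ThresholdConfig:
    """All classification thresholds, defaulting to the published analysis.

    ``region_min_rpm`` defaults to 10 (the analysis narrative); the
    alternative floor of 5 that appears in the processing description can be
    set here instead.
    """

    gene_on_fc: float = 3.0
    gene_expr_min_fpkm: float = 5.0
    gene_p: float = 0.05  # adjusted
    region_fc: float = 5.0
    region_min_rpm: float = 10.0
    region_p: float = 0.01
    sub_full_max_fc: float = 2.0
    sub_partial_max_fc: float = 5.0
    restore_fc: float = 2.0
    repeat_fc_tiers: tuple[float, ...] = (1.0, 2.0, 5.0)
    repeat_min_vst: float = 5.0

    def __post_init__(self) -> None:
        if not self.sub_full_max_fc < self.sub_partial_max_fc:
            raise ValueError("sub_full_max_fc must be < sub_partial_max_fc")


@dataclass
class ClassifiedFeature:
    """A gene, merged region or repeat with its taxonomy label and statistics."""

    feature_id: str
    kind: str  # gene | region | repeat
    axis: str  # EGA | PFF
    label: str
    fc_primary: float
    fc_secondary: float = float("nan")
    p: float = float("nan")
    padj: float = float("nan")
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    restored_by: set[str] = field(default_factory=set)
    extras: dict = field(default_factory=dict)

    @property
    def resistant(self) -> bool:
        """EGA-OFF and PFF-ON features are the reprogramming-resistant set."""
        return (self.axis == EGA_AXIS and self.label == OFF) or (
            self.axis == PFF_AXIS and self.label == ON
        )


def ega_sublabel(fc_secondary: float, thr: ThresholdConfig) -> str:
    if fc_secondary <= thr.sub_full_max_fc:
        return FULLY_ON
    if fc_secondary <= thr.sub_partial_max_fc:
        return PARTIALLY_ON
    return OFF


def pff_sublabel(fc_secondary: float, thr: ThresholdConfig) -> str:
    if fc_secondary >= thr.sub_partial_max_fc:
        return FULLY_OFF
    if fc_secondary >= thr.sub_full_max_fc:
        return PARTIALLY_OFF
    return ON


def _classify_genes_axis(
    expr: ExpressionTable,
    diff: pd.DataFrame,
    thr: ThresholdConfig,
    axis: str,
    eps: float,
    groups: tuple[str, str, str],
    norm: ExpressionTable | None,
) -> list[ClassifiedFeature]:
    num, den, sec_den = groups
    for g in groups:
        expr.group_means(g)  # raises on missing group
    fc_src = norm if norm is not None else expr
    m_num = fc_src.group_means(num)
    m_den = fc_src.group_means(den)
    m_sec = fc_src.group_means(sec_den)
    floor = expr.group_means(num)
    sub = ega_sublabel if axis == EGA_AXIS else pff_sublabel
    out: list[ClassifiedFeature] = []
    for fid in expr.values.index:
        fc1 = float(fold_change(m_num[fid], m_den[fid], eps))
        padj = float(diff.loc[fid, "padj"]) if fid in diff.index else float("nan")
        p = float(diff.loc[fid, "p"]) if fid in diff.index else float("nan")
        passed = (
            fc1 > thr.gene_on_fc
            and floor[fid] > thr.gene_expr_min_fpkm
            and padj < thr.gene_p
        )
        fc2 = float(fold_change(m_num[fid], m_sec[fid], eps))
        out.append(
            ClassifiedFeature(
                feature_id=str(fid),
                kind="gene",
                axis=axis,
                label=sub(fc2, thr) if passed else NONE,
                fc_primary=fc1,
                fc_secondary=fc2,
                p=p,
                padj=padj,
                extras={"mean_floor": float(floor[fid])},
            )
        )
    return out


def classify_ega_genes(
    expr: ExpressionTable,
    diff: pd.DataFrame,
    thr: ThresholdConfig | None = None,
    eps: float = DEFAULT_PSEUDOCOUNT,
    groups: tuple[str, str, str] = ("IVO4c", "IVO2c", "SCNT4c"),
    norm: ExpressionTable | None = None,
) -> list[ClassifiedFeature]:
    """EGA-axis gene taxonomy.

    A gene is EGA-class iff FC(IVO4c/IVO2c) > ``gene_on_fc``, mean FPKM in
    IVO4c exceeds ``gene_expr_min_fpkm`` and the adjusted p of the
    IVO4c-vs-IVO2c test is below ``gene_p``; the subgroup comes from
    FC(IVO4c/SCNT4c).  ``diff`` is the gene test table for IVO4c vs IVO2c
    (see :func:`rrscan.differential.gene_diff_table`).  Fold changes are
    computed on ``norm`` (size-factor-normalized means, see
    :func:`rrscan.quantify.mor_table`) when given, falling back to the FPKM
    table itself; the expression floor always uses FPKM.
    """
    return _classify_genes_axis(expr, diff, thr or ThresholdConfig(), EGA_AXIS, eps, groups, norm)


def classify_pff_genes(
    expr: ExpressionTable,
    diff: pd.DataFrame,
    thr: ThresholdConfig | None = None,
    eps: float = DEFAULT_PSEUDOCOUNT,
    groups: tuple[str, str, str] = ("PFF", "IVO4c", "SCNT4c"),
    norm: ExpressionTable | None = None,
) -> list[ClassifiedFeature]:
    """PFF-axis gene taxonomy (donor-cell silencing).

    A gene is PFF-class iff FC(PFF/IVO4c) > ``gene_on_fc``, mean FPKM in
    PFF exceeds the floor and padj < ``gene_p``; the subgroup comes from
    FC(PFF/SCNT4c).  ``diff`` is the gene test table for PFF vs IVO4c.
    ``norm`` as in :func:`classify_ega_genes`.
    """
    return _classify_genes_axis(expr, diff, thr or ThresholdConfig(), PFF_AXIS, eps, groups, norm)


def _merge_passing(windows: list[Window], mask: np.ndarray) -> list[list[int]]:
    """Group indices of passing windows into maximal overlapping/bookended runs."""
    idx = [i for i in range(len(windows)) if mask[i]]
    idx.sort(key=lambda i: (windows[i].chrom, windows[i].start))
    runs: list[list[int]] = []
    for i in idx:
        w = windows[i]
        if runs:
            last = windows[runs[-1][-1]]
            cur_end = max(windows[j].end for j in runs[-1])
            if w.chrom == last.chrom and w.start <= cur_end:
                runs[-1].append(i)
                continue
        runs.append([i])
    return runs


def classify_regions(
    window_counts: CountMatrix,
    windows: list[Window],
    thr: ThresholdConfig | None = None,
    axis: str = EGA_AXIS,
    eps: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[ClassifiedFeature], CountMatrix]:
    """Screen sliding windows, merge them into regions, and label the regions.

    Windows pass the primary screen when FC > ``region_fc``, pooled RPM in
    the floor group exceeds ``region_min_rpm`` and the Fisher p is below
    ``region_p``.  Overlapping or bookended passing windows merge into
    maximal regions; region-level counts are re-pooled over the member
    windows of the merged span and the subgroup label is assigned from the
    recomputed secondary-contrast FC with the same interval rules as genes.

    Returns the classified regions and the region-level count matrix used
    for downstream restoration scoring and profiles.
    """
    thr = thr or ThresholdConfig()
    if axis == EGA_AXIS:
        num, den, floor_group, sec_den = "IVO4c", "IVO2c", "IVO4c", "SCNT4c"
        sub = ega_sublabel
    elif axis == PFF_AXIS:
        num, den, floor_group, sec_den = "PFF", "IVO4c", "PFF", "SCNT4c"
        sub = pff_sublabel
    else:
        raise ValueError(f"unknown axis {axis!r}")

    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    windows = [windows[i] for i in order]
    counts = window_counts.counts.iloc[order]
    matrix = CountMatrix(counts, window_counts.samples)

    diff = window_diff_table(matrix, num, den, eps=eps)
    pooled_floor, size_floor = matrix.pooled(floor_group)
    floor_rpm = pooled_floor.to_numpy(float) * 1e6 / size_floor
    mask = (
        (diff["fc"].to_numpy() > thr.region_fc)
        & (floor_rpm > thr.region_min_rpm)
        & (diff["p"].to_numpy() < thr.region_p)
    )

    runs = _merge_passing(windows, mask)
    features: list[ClassifiedFeature] = []
    region_rows = []
    region_ids = []
    for run in runs:
        chrom = windows[run[0]].chrom
        start = min(windows[i].start for i in run)
        end = max(windows[i].end for i in run)
        rid = f"{chrom}:{start}-{end}"
        pooled = matrix.counts.iloc[run].sum(axis=0)  # per-sample region counts
        region_rows.append(pooled)
        region_ids.append(rid)
        features.append(
            ClassifiedFeature(
                feature_id=rid, kind="region", axis=axis, label=NONE,
                fc_primary=float("nan"), chrom=chrom, start=start, end=end,
            )
        )

    region_counts = CountMatrix(
        pd.DataFrame(region_rows, index=pd.Index(region_ids, name="region_id"))
        if region_rows
        else pd.DataFrame(
            np.zeros((0, matrix.counts.shape[1]), dtype=int),
            columns=matrix.counts.columns,
            index=pd.Index([], name="region_id"),
        ),
        matrix.samples,
    )

    if region_rows:
        def pooled_rpm(group: str) -> np.ndarray:
            c, s = region_counts.pooled(group)
            return c.to_numpy(float) * 1e6 / s

        rpm_num = pooled_rpm(num)
        rpm_den = pooled_rpm(den)
        rpm_sec = pooled_rpm(sec_den)
        c_num, s_num = region_counts.pooled(num)
        c_den, s_den = region_counts.pooled(den)
        for i, feat in enumerate(features):
            feat.fc_primary = float(fold_change(rpm_num[i], rpm_den[i], eps))
            feat.fc_secondary = float(fold_change(rpm_num[i], rpm_sec[i], eps))
            feat.p = fisher_window_test(
                int(c_num.iloc[i]), int(s_num - c_num.iloc[i]),
                int(c_den.iloc[i]), int(s_den - c_den.iloc[i]),
            )
            feat.label = sub(feat.fc_secondary, thr)
    return features, region_counts


def assess_restoration(
    classified: list[ClassifiedFeature],
    expr: ExpressionTable,
    treated_group: str,
    scnt_group: str = "SCNT4c",
    thr: ThresholdConfig | None = None,
    eps: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, float]:
    """Score treatment restoration of resistant features.

    An EGA-OFF feature is reactivated when FC(treated/SCNT4c) >
    ``restore_fc``; a PFF-ON feature is silenced when FC(treated/SCNT4c) <
    ``1/restore_fc`` (strict).  Restored features get ``treated_group``
    added to their ``restored_by`` set.  Returns the restored fraction per
    resistant class, keyed ``"EGA_OFF"`` and ``"PFF_ON"`` (present only when
    the class has members).
    """
    thr = thr or ThresholdConfig()
    m_treated = expr.group_means(treated_group)
    m_scnt = expr.group_means(scnt_group)
    tallies: dict[str, list[int]] = {}
    for feat in classified:
        if not feat.resistant:
            continue
        if feat.feature_id not in m_treated.index:
            continue
        fc = float(fold_change(m_treated[feat.feature_id], m_scnt[feat.feature_id], eps))
        if feat.axis == EGA_AXIS:
            key, restored = "EGA_OFF", fc > thr.restore_fc
        else:
            key, restored = "PFF_ON", fc < 1.0 / thr.restore_fc
        if restored:
            feat.restored_by.add(treated_group)
        tallies.setdefault(key, []).append(int(restored))
    return {k: float(np.mean(v)) for k, v in tallies.items()}


def classify_repeats(
    vst_expr: ExpressionTable,
    families: pd.Series,
    thr: ThresholdConfig | None = None,
    eps: float = DEFAULT_PSEUDOCOUNT,
    groups: tuple[str, str] = ("IVO4c", "IVO2c"),
) -> tuple[list[ClassifiedFeature], dict[str, int]]:
    """EGA-activated repeat elements in cumulative fold-change tiers.

    A repeat is EGA-ON when the FC of de-logged VST group means (IVO4c vs
    IVO2c) exceeds the lowest tier and mean VST in IVO4c exceeds
    ``repeat_min_vst``.  The stored label is the highest tier passed
    (``"GT1"``, ``"GT2"``, ``"GT5"`` for the default tiers); tier *sets* are
    cumulative, so GT5 members also belong to the >1 and >2 sets.  The
    summary counts EGA-ON repeats per repeat class, taken from the
    ``class/family`` annotation string (class ``"unknown"`` when absent).
    """
    thr = thr or ThresholdConfig()
    num, den = groups
    delogged = delog_vst(vst_expr.values)
    linear = ExpressionTable(delogged.clip(lower=0), "RPM", vst_expr.samples)  # unit-less linear scale
    m_num = linear.group_means(num)
    m_den = linear.group_means(den)
    vst_floor = vst_expr.group_means(num)
    tiers = sorted(thr.repeat_fc_tiers)
    out: list[ClassifiedFeature] = []
    summary: dict[str, int] = {}
    for fid in vst_expr.values.index:
        fc = float(fold_change(m_num[fid], m_den[fid], eps))
        is_on = fc > tiers[0] and float(vst_floor[fid]) > thr.repeat_min_vst
        if is_on:
            top = max(t for t in tiers if fc > t)
            label = f"GT{top:g}"
        else:
            label = NONE
        fam = families.get(fid, None)
        klass = str(fam).split("/")[0] if fam is not None and not pd.isna(fam) else "unknown"
        out.append(
            ClassifiedFeature(
                feature_id=str(fid), kind="repeat", axis=EGA_AXIS, label=label,
                fc_primary=fc, extras={"family": fam, "class": klass,
                                       "vst_floor": float(vst_floor[fid])},
            )
        )
        if is_on:
            summary[klass] = summary.get(klass, 0) + 1
    return out, summary


def tier_sets(repeats: list[ClassifiedFeature], thr: ThresholdConfig | None = None) -> dict[str, set[str]]:
    """Cumulative tier membership: each set holds EGA-ON repeats with FC above the tier."""
    thr = thr or ThresholdConfig()
    sets: dict[str, set[str]] = {f"GT{t:g}": set() for t in thr.repeat_fc_tiers}
    for r in repeats:
        if r.label == NONE:
            continue
        for t in thr.repeat_fc_tiers:
            if r.fc_primary > t:
                sets[f"GT{t:g}"].add(r.feature_id)
    return sets


def classified_to_frame(features: list[ClassifiedFeature]) -> pd.DataFrame:
    """Flatten classified features into a DataFrame (TSV-friendly)."""
    rows = []
    for f in features:
        rows.append(
            {
                "feature_id": f.feature_id,
                "kind": f.kind,
                "axis": f.axis,
                "label": f.label,
                "fc_primary": f.fc_primary,
                "fc_secondary": f.fc_secondary,
                "p": f.p,
                "padj": f.padj,
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "restored_by": ",".join(sorted(f.restored_by)),
            }
        )
    return pd.DataFrame(rows)
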