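import numpy as np
import pandas as pd
import pytest

from rrscan.classify import (
    EGA_AXIS,
    FULLY_OFF,
    FULLY_ON,
    NONE,
    OFF,
    ON,
    PARTIALLY_OFF,
    PARTIALLY_ON,
    PFF_AXIS,
    ClassifiedFeature,
    ThresholdConfig,
    assess_restoration,
    classify_ega_genes,
    classify_pff_genes,
    classify_regions,
    classify_repeats,
    ega_sublabel,
    pff_sublabel,
    tier_sets,
)
from rrscan.genome import Window
from rrscan.quantify import CountMatrix, ExpressionTable, vst


def expr_table(rows: dict, groups, unit="FPKM") -> ExpressionTable:
    """One sample per group, values given per feature."""
    df = pd.DataFrame(rows, index=[f"{g}_r1" for g in groups]).T
    samples = pd.DataFrame(
        {"group": groups, "replicate": 1, "library_size": 1e6},
        index=df.columns,
    )
    return ExpressionTable(df, unit, samples)


GROUPS3 = ["IVO2c", "IVO4c", "SCNT4c"]
PGROUPS = ["PFF", "IVO4c", "SCNT4c"]


def diff_frame(padj: dict) -> pd.DataFrame:
    return pd.DataFrame({"p": padj, "padj": padj})


class TestGeneTaxonomy:
    def test_ega_off_assignment(self):
        # fc_primary 4, floor 6 FPKM, padj 0.01, fc_secondary 6 -> OFF
        expr = expr_table({"g": [1.5, 6.0, 0.75]}, GROUPS3)
        feats = classify_ega_genes(expr, diff_frame({"g": 0.01}), eps=0)
        (f,) = feats
        assert f.axis == EGA_AXIS and f.label == OFF
        assert f.fc_primary == pytest.approx(4.0)

    def test_expression_floor_blocks_classification(self):
        expr = expr_table({"g": [1.0, 4.9, 1.0]}, GROUPS3)
        (f,) = classify_ega_genes(expr, diff_frame({"g": 0.001}), eps=0)
        assert f.label == NONE

    def test_padj_gate_blocks_classification(self):
        expr = expr_table({"g": [1.0, 50.0, 1.0]}, GROUPS3)
        (f,) = classify_ega_genes(expr, diff_frame({"g": 0.2}), eps=0)
        assert f.label == NONE

    def test_ega_boundary_fc2_is_fully_on(self):
        # secondary FC exactly 2 -> FULLY_ON (inclusive boundary)
        expr = expr_table({"g": [1.0, 20.0, 10.0]}, GROUPS3)
        (f,) = classify_ega_genes(expr, diff_frame({"g": 0.001}), eps=0)
        assert f.fc_secondary == pytest.approx(2.0) and f.label == FULLY_ON

    def test_pff_on_assignment(self):
        expr = expr_table({"g": [50.0, 5.0, 33.3333333]}, PGROUPS)
        (f,) = classify_pff_genes(expr, diff_frame({"g": 1e-4}), eps=0)
        assert f.axis == PFF_AXIS and f.label == ON

    def test_pff_boundary_fc5_is_fully_off(self):
        expr = expr_table({"g": [50.0, 5.0, 10.0]}, PGROUPS)
        (f,) = classify_pff_genes(expr, diff_frame({"g": 1e-4}), eps=0)
        assert f.fc_secondary == pytest.approx(5.0) and f.label == FULLY_OFF

    def test_pff_boundary_fc2_is_partially_off(self):
        expr = expr_table({"g": [50.0, 5.0, 25.0]}, PGROUPS)
        (f,) = classify_pff_genes(expr, diff_frame({"g": 1e-4}), eps=0)
        assert f.fc_secondary == pytest.approx(2.0) and f.label == PARTIALLY_OFF

    def test_missing_group_rejected(self):
        expr = expr_table({"g": [1.0, 2.0]}, ["IVO2c", "IVO4c"])
        with pytest.raises(KeyError):
            classify_ega_genes(expr, diff_frame({"g": 0.5}))

    def test_sublabel_partition(self):
        # every secondary FC receives exactly one label per axis
        for fc in np.linspace(0.1, 10, 67):
            assert ega_sublabel(fc, ThresholdConfig()) in (FULLY_ON, PARTIALLY_ON, OFF)
            assert pff_sublabel(fc, ThresholdConfig()) in (FULLY_OFF, PARTIALLY_OFF, ON)


def window_matrix(counts_by_group: dict, windows):
    """Build a window CountMatrix; one replicate per group, library 1e6."""
    cols = {f"{g}_r1": v for g, v in counts_by_group.items()}
    df = pd.DataFrame(cols, index=[f"{w.chrom}:{w.start}-{w.end}" for w in windows])
    samples = pd.DataFrame(
        {
            "group": list(counts_by_group),
            "replicate": 1,
            "library_size": 1e6,
        },
        index=df.columns,
    )
    return CountMatrix(df, samples)


class TestRegionMerge:
    def make(self, act):
        """Four windows; ``act`` marks which are activated in IVO4c."""
        ws = [
            Window("c", 0, 50_000),
            Window("c", 20_000, 70_000),
            Window("c", 100_000, 150_000),
            Window("c", 200_000, 250_000),
        ]
        base = np.full(4, 100)
        hi = np.where(act, 10_000, 100)
        m = window_matrix(
            {"IVO2c": base, "IVO4c": hi, "SCNT4c": base, "PFF": base}, ws
        )
        return ws, m

    def test_overlapping_passing_windows_merge(self):
        ws, m = self.make(np.array([True, True, False, False]))
        regions, _ = classify_regions(m, ws)
        assert [(r.chrom, r.start, r.end) for r in regions] == [("c", 0, 70_000)]

    def test_isolated_window_gives_minimum_region(self):
        ws, m = self.make(np.array([False, False, True, False]))
        regions, _ = classify_regions(m, ws)
        (r,) = regions
        assert r.end - r.start == 50_000

    def test_merge_idempotent_on_merged_regions(self):
        ws, m = self.make(np.array([True, True, False, True]))
        regions, rc = classify_regions(m, ws)
        merged = [Window(r.chrom, r.start, r.end) for r in regions]
        again, _ = classify_regions(rc, merged)
        assert [(r.chrom, r.start, r.end) for r in again] == [
            (w.chrom, w.start, w.end) for w in merged
        ]

    def test_region_label_from_repooled_secondary_fc(self):
        ws, m = self.make(np.array([True, True, False, False]))
        regions, _ = classify_regions(m, ws)
        assert regions[0].label == OFF  # SCNT4c stays at baseline -> FC >> 5

    def test_unsorted_windows_sorted_internally(self):
        ws, m = self.make(np.array([True, True, False, False]))
        order = [3, 1, 0, 2]
        m2 = CountMatrix(m.counts.iloc[order], m.samples)
        regions, _ = classify_regions(m2, [ws[i] for i in order])
        assert [(r.start, r.end) for r in regions] == [(0, 70_000)]


class TestRestoration:
    def feats(self):
        return [
            ClassifiedFeature("a", "gene", EGA_AXIS, OFF, 10.0),
            ClassifiedFeature("b", "gene", PFF_AXIS, ON, 10.0),
        ]

    def test_ega_off_restored_above_fc2(self):
        expr = expr_table({"a": [2.5, 1.0], "b": [1.0, 1.0]}, ["SCNT4c-KG", "SCNT4c"])
        feats = self.feats()
        frac = assess_restoration(feats, expr, "SCNT4c-KG", eps=0)
        assert frac["EGA_OFF"] == 1.0
        assert feats[0].restored_by == {"SCNT4c-KG"}

    def test_pff_on_boundary_half_not_silenced(self):
        # FC exactly 0.5 is NOT silenced (strict <)
        expr = expr_table({"a": [1.0, 1.0], "b": [0.5, 1.0]}, ["SCNT4c-KG", "SCNT4c"])
        frac = assess_restoration(self.feats(), expr, "SCNT4c-KG", eps=0)
        assert frac["PFF_ON"] == 0.0

    def test_missing_treated_group_rejected(self):
        expr = expr_table({"a": [1.0], "b": [1.0]}, ["SCNT4c"])
        with pytest.raises(KeyError):
            assess_restoration(self.feats(), expr, "SCNT4c-KG")


class TestRepeats:
    def vst_table(self, v2c, v4c):
        df = pd.DataFrame({"IVO2c_r1": v2c, "IVO4c_r1": v4c},
                          index=[f"r{i}" for i in range(len(v2c))])
        samples = pd.DataFrame(
            {"group": ["IVO2c", "IVO4c"], "replicate": 1, "library_size": 1e6},
            index=df.columns,
        )
        return ExpressionTable(df, "VST", samples)

    def fam(self, n):
        return pd.Series(["LTR/ERV1"] * n, index=[f"r{i}" for i in range(n)])

    def test_tier_assignment(self):
        # de-logged means: FC 1.5 -> GT1; FC 6 -> GT5; floor VST > 5
        v2c = np.log2(np.array([100, 100]) + 1)
        v4c = np.log2(np.array([150, 600]) + 1)
        feats, _ = classify_repeats(self.vst_table(v2c, v4c), self.fam(2), eps=0)
        assert feats[0].label == "GT1"
        assert feats[1].label == "GT5"

    def test_vst_floor_blocks(self):
        v2c = np.log2(np.array([10.0]) + 1)
        v4c = np.log2(np.array([25.0]) + 1)  # VST ~4.7 < 5
        feats, _ = classify_repeats(self.vst_table(v2c, v4c), self.fam(1), eps=0)
        assert feats[0].label == NONE

    def test_tier_sets_nested(self, dataset):
        table = vst(dataset.repeat_counts)
        feats, _ = classify_repeats(table, dataset.repeats["family"])
        sets = tier_sets(feats)
        assert sets["GT5"] <= sets["GT2"] <= sets["GT1"]

    def test_class_summary_counts_families(self):
        v2c = np.log2(np.array([100, 100]) + 1)
        v4c = np.log2(np.array([600, 600]) + 1)
        fam = pd.Series(["LTR/ERV1", "satellite/SSRS1"], index=["r0", "r1"])
        _, summary = classify_repeats(self.vst_table(v2c, v4c), fam, eps=0)
        assert summary == {"LTR": 1, "satellite": 1}

    def test_missing_family_is_unknown_class(self):
        v2c = np.log2(np.array([100.0]) + 1)
        v4c = np.log2(np.array([600.0]) + 1)
        _, summary = classify_repeats(self.vst_table(v2c, v4c), pd.Series(dtype=object), eps=0)
        assert summary == {"unknown": 1}


class TestAxisPartition:
    def test_each_gene_gets_exactly_one_label_per_axis(self, dataset):
        from rrscan.pipeline import classify_gene_axes

        _, ega, pff = classify_gene_axes(dataset)
        for feats, allowed in ((ega, {FULLY_ON, PARTIALLY_ON, OFF, NONE}),
                               (pff, {FULLY_OFF, PARTIALLY_OFF, ON, NONE})):
            seen = {}
            for f in feats:
                assert f.label in allowed
                assert f.feature_id not in seen
                seen[f.feature_id] = f.label
            assert len(seen) == len(dataset.gene_counts.counts)
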