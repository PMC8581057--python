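# Methods

`rrscan` identifies *reprogramming-resistant* genes and genomic regions in
somatic-cell nuclear-transfer (SCNT) embryos: features that should switch
state at embryonic genome activation (EGA) but fail to do so in clones.
The pipeline compares six sample groups — donor pig fetal fibroblasts
(PFF), in-vivo two- and four-cell embryos (IVO2c, IVO4c), cloned four-cell
embryos (SCNT4c) and two epigenetically treated cloned groups (SCNT4c-KG:
KDM4A mRNA + GSK126; SCNT4c-TDG: transient TDG induction) — across RNA
counts, sliding-window region expression, repeat-element expression,
histone-mark ChIP coverage and per-CpG bisulfite calls.

## Classification model

Two axes, each a primary screen followed by a fold-change (FC) subgrouping
against the cloned embryo:

**EGA axis (activation).** A gene is EGA-class when
FC(IVO4c/IVO2c) > 3, mean FPKM in IVO4c > 5, and BH-adjusted p < 0.05.
The subgroup comes from FC(IVO4c/SCNT4c): fully activated (FC ≤ 2),
partially activated (2 < FC ≤ 5), EGA-OFF (FC > 5).

**PFF axis (donor silencing).** A gene is PFF-class when
FC(PFF/IVO4c) > 3, mean FPKM in PFF > 5, adjusted p < 0.05; subgroup from
FC(PFF/SCNT4c): fully silenced (FC ≥ 5), partially (2 ≤ FC < 5), PFF-ON
(FC < 2). Boundary inclusivity follows the published interval conventions
exactly; note the two axes close their boundaries on opposite sides.

EGA-OFF ∪ PFF-ON is the resistant set. A treated group *restores* an
EGA-OFF feature when FC(treated/SCNT4c) > 2 and *silences* a PFF-ON
feature when FC(treated/SCNT4c) < 0.5 (strict).

Regions use the same taxonomy on 50-kb windows stepped every 20 kb
(partial terminal windows dropped, so regions are never shorter than one
window) with region thresholds FC > 5, pooled RPM > 10 in the reference
group, Fisher p < 0.01. Passing windows that overlap or bookend merge into
maximal regions; counts are re-pooled over the merged span and the
subgroup label is recomputed there, because regions — not windows — are
the reported unit. The source analysis states the RPM floor as 10 in its
narrative and 5 in its processing description; we default to 10 and expose
the value in `ThresholdConfig.region_min_rpm`. Whether windows or merged
spans were the published unit is not stated; the published region lengths
(minimum exactly one window) imply merging, which is what we implement.

Repeat elements are screened on variance-stabilized (VST) expression:
EGA-ON when FC of de-logged VST group means (IVO4c/IVO2c) > 1 and mean VST
in IVO4c > 5, reported in cumulative tiers FC > 1, > 2, > 5.

## Statistics

**Fold change.** Always `(a + ε) / (b + ε)` with pseudocount ε = 0.5 in
the normalized unit, so OFF states never divide by zero; ε is
configurable everywhere.

**Normalization for fold changes.** FPKM/RPM divide by the library size,
which is confounded at EGA: when a large gene set rises ten-fold in one
direction it inflates the library size and compresses every ratio. Gene
fold changes and the gene test therefore normalize with median-of-ratios
size factors (the estimator DESeq-style tools use), which are anchored on
the unchanged majority of genes; FPKM is used only for the expression
floor. This breaks down if half or more of the features shift — the
synthetic defaults keep planted fractions well below that.

**Window test.** Replicate counts are pooled within each group (the
simplest model consistent with a single Fisher p per window) and tested
with the two-sided Fisher exact test of window reads vs the rest of the
library. The two-sided p sums all hypergeometric table probabilities ≤
the observed one, ties included. For table totals ≤ 500 the computation
is exact integer arithmetic (numerators compared as integers, one final
float division); above that, log-gamma evaluation with a 1e-12 relative
tie gate. A zero margin returns p = 1. Window p-values are reported
unadjusted by default (the region screen uses p < 0.01); BH is available.

**Gene test.** A two-group Wald test on negative-binomial counts
(`var = μ + φμ²`). Counts are scaled to a common depth, per-gene φ is
estimated by method of moments pooled across both groups and floored at
1e-8, and the log fold change is tested with the delta-method variance.
The statistic is referred to a Student t with n_A + n_B − 2 degrees of
freedom rather than a normal: with three replicates per group the moment
variance estimate is noisy, the normal reference rejects ~13% of nulls at
α = 0.05, and the t reference restores ~5.5% (measured by simulation at
μ = 100, φ = 0.1, 3 vs 3). No information is shared across genes — no
shrinkage or trended dispersion, deliberately — so with only two
replicates per group (one residual df per group) the test cannot reach
BH-adjusted significance; three or more replicates are required for the
gene screen, and the bundled pipeline defaults to three.

**Multiplicity.** Benjamini–Hochberg step-up, via statsmodels.

**Intensity comparisons.** Two-tailed Student t (pooled variance;
Welch behind a flag), stars at 0.05 / 0.01 / 0.001. Zero-variance
degenerate input: equal means → p = 1, unequal → p = 0.

## Signal aggregation

ChIP coverage lives on a fixed 200-bp binning. Interval intensity is
`log2((d_chip + ε) / (d_input + ε))` with densities in RPM per kb and
ε = 0.1 RPM/kb. The source describes "normalized by input" without fixing
ratio vs subtraction; the log ratio is chosen because it is symmetric
around zero and exactly invariant to sequencing depth, and all published
comparisons used here are monotone-invariant to that choice. Region
meta-profiles rescale each body to 100 bins between two 100-kb flanks of
fifty 2-kb bins; TSS profiles use 100 fixed-width bins over ±5 kb.
Minus-strand features are orientation-flipped. Bins clipped at chromosome
ends become NaN and are excluded from means, never zero-filled.

Methylation level of an interval is the coverage-weighted pooled ratio
Σ methylated / Σ (methylated + unmethylated) over contained CpGs with
coverage ≥ `min_cov` (default 1 — no coverage filter). Pooling is robust
at the ~10× per-CpG coverage of ultra-low-input bisulfite data; the
unweighted mean of per-CpG ratios is available behind `per_cpg_mean`.
"Average ratio" is ambiguous between the two; pooled is the default.
Intervals with no qualifying CpG are undefined (NaN), not 0. Promoters
(TSS ± 5 kb, clipped) are "with CGI" iff they overlap a CpG island by
≥ 1 bp under half-open coordinates.

The VST is implemented as `log2(count / size_factor + 1)` with
median-of-ratios size factors — a shifted log, not a re-implementation of
any package's parametric fit. No numeric equivalence to a specific tool
is claimed; the transform is validated by its properties (strict
monotonicity in the count, variance flattening, de-log invertibility).

## Synthetic data

The generator plants a complete multi-omic experiment whose truth table
records every planted label. Defaults: 2 chromosomes × 10 Mb, 1,000 genes,
300 repeats, NB counts with baseline mean 100 and dispersion φ = 0.1
(typical bulk RNA-seq overdispersion), activation fold change 10, ChIP
enrichment 4×, methylation levels 0.8 / 0.5 / 0.2 (donor background /
embryo background / hypomethylated), 60% of resistant features restored
in treated groups. Fractions convert to counts by `floor(frac × n)` with
a seed-deterministic shuffle, so planted label counts are exact, and one
`numpy` Generator drives everything, so equal seeds give byte-identical
output files.

Regions are planted as contiguous blocks of 10-kb tiles (tile NB counts
are summed into sliding windows, so overlapping windows share reads as
they would with real alignments). Blocks start on the 20-kb step grid
with lengths ≡ 10 kb (mod 20 kb) in 100–200 kb, which keeps every
partially overlapping window's planted fold change well away from the
FC = 5 screen boundary and makes ≤ 20 kb boundary recovery a meaningful
target. ChIP tracks are Poisson per 200-bp bin: flat input at 5
reads/bin, chip enriched 4× over resistant blocks and resistant-gene
promoters. CpG sites sit every 200 bp at Poisson(10) coverage with
binomial methylated counts; CpG islands are planted at half the gene
promoters and stay hypomethylated; the TDG-treated group additionally
demethylates resistant features.

What the generator does **not** emulate: real sequence content, mappability
and GC structure, read-level noise, gene-length–dependent count variance
coupling, fragmented/nested repeat annotations, strand-specific bisulfite
conversion error, and replicate-level batch effects. Passing tests
therefore demonstrate that the statistics and bookkeeping are correct
under the stated model, not that thresholds are optimal for real
pig-embryo libraries.

## Problem sizes

The bundled tests and the acceptance script run at 1,000 genes × 18
samples, ~1,000 windows, 300 repeats, 2,000-gene null calibrations and
200-CpG methylation intervals — sizes chosen so every planted effect is
detectable against its sampling error with comfortable margins while the
entire suite completes in seconds.

## Known limitations

* Two replicates per group cannot reach gene-level significance (see
  above); the window Fisher test, being pooled, is unaffected.
* Merged-region re-pooling sums member-window counts, so reads in window
  overlaps are counted more than once; this cancels in fold changes
  (both groups are inflated identically) but region "counts" are not read
  counts.
* Median-of-ratios factors assume a stable majority of features.
* The Fisher/NB/t machinery is two-group only; multi-factor designs are
  out of scope.
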