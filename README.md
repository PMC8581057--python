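# rrscan

Scan multi-omic data from somatic-cell nuclear-transfer (SCNT) embryos for
**reprogramming-resistant** genes and genomic regions.

Cloned embryos frequently stall at the maternal-to-zygotic transition
because the donor genome is incompletely reprogrammed: genes that should
switch on at embryonic genome activation (EGA) stay silent, and
donor-cell genes that should switch off stay expressed. `rrscan`
implements the comparative analysis that identifies these features from
count data — for pig, that means contrasting in-vivo two- and four-cell
embryos (IVO2c, IVO4c), cloned four-cell embryos (SCNT4c), the donor
fibroblasts (PFF), and treated clones (SCNT4c-KG, SCNT4c-TDG) — together
with a synthetic-data generator that plants ground truth so every stage is
verifiable without external downloads.

## What it computes

* **Gene taxonomy.** EGA-class genes: FC<sup>IVO4c/IVO2c</sup> > 3,
  FPKM<sub>IVO4c</sub> > 5, adjusted p < 0.05; subgrouped by
  FC<sup>IVO4c/SCNT4c</sup> into fully activated (FC ≤ 2), partially
  (2 < FC ≤ 5) and **EGA-OFF** (FC > 5). PFF-class genes symmetrically on
  FC<sup>PFF/IVO4c</sup>, with **PFF-ON** (FC<sup>PFF/SCNT4c</sup> < 2)
  the donor genes clones fail to silence. EGA-OFF ∪ PFF-ON is the
  resistant set.
* **Region taxonomy.** The same screen on 50-kb sliding windows (20-kb
  step, two-sided Fisher exact test on pooled counts, FC > 5, RPM > 10,
  p < 0.01), with passing windows merged into maximal regions and
  relabeled from re-pooled counts.
* **Restoration scoring.** A treated group restores an EGA-OFF feature
  when FC<sup>treated/SCNT4c</sup> > 2 and silences a PFF-ON feature when
  FC < 0.5.
* **Repeat tiers.** EGA-activated repeat elements on VST expression
  (FC > 1, VST > 5) in cumulative tiers FC > 1 / > 2 / > 5, summarized by
  repeat class.
* **Histone-mark intensity.** Input-normalized log2 ChIP enrichment
  (reads normalized by input, total mapped reads and region length) as
  meta-profiles over regions ± 100-kb flanks and TSSs ± 5 kb, with
  Student-t group comparisons.
* **CpG methylation.** Coverage-weighted methylated/total ratios over
  regions, profile bins, and CGI-stratified promoters.
* **Statistics.** Pseudocount fold changes, exact two-sided Fisher test,
  a replicate-aware negative-binomial Wald test with BH adjustment, and
  the two-tailed Student t test. See `docs/methods.md` for the model
  details and numerical choices.

## Worked example

Simulate a full experiment (two 10-Mb chromosomes, 1,000 genes, 300
repeats, planted resistant blocks, ChIP and bisulfite tracks; three
replicates per group) and run every stage:

```sh
rrscan pipeline --seed 7 --out demo/
```

prints, among other fields:

```json
{
  "n_ega_class_genes": 198,
  "n_ega_off_genes": 80,
  "n_pff_class_genes": 200,
  "n_pff_on_genes": 59,
  "n_resistant_regions": 5,
  "n_ega_on_repeats": 132,
  "restored_fractions": {
    "gene_EGA_OFF_SCNT4c-KG": 0.6,
    "gene_PFF_ON_SCNT4c-KG": 0.5932203389830508
  },
  "chip": {
    "resistant_body_intensity": 1.481219751097293,
    "resistant_flank_intensity": -0.22064944262721614
  },
  "methylation": {
    "resistant_region_meth_SCNT4c": 0.7556399004665485,
    "resistant_region_meth_SCNT4c-TDG": 0.22185428547154373
  }
}
```

Reading: of 200 planted EGA-class genes the screen recovered 198, and 80
of them are EGA-OFF (the generator planted 80); the treated group
restored 60% of EGA-OFF genes, matching the planted restoration rate.
Resistant regions carry ~1.7 log2 units more repressive-mark signal in
their bodies than their flanks (4-fold planted enrichment) and stay
hypermethylated in clones (0.76) until TDG induction demethylates them
(0.22). `demo/` holds the classified tables (TSV/BED), meta-profile
matrices, the full fixture, and `summary.json` with exactly the numbers
above; rerunning with the same seed reproduces every file byte for byte.

Individual stages are available as `rrscan simulate | windows |
diff-windows | diff-genes | classify-genes | classify-regions |
classify-repeats | restore | chip-profile | meth-level | meth-promoters`,
and everything is importable from Python (`import rrscan`).

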