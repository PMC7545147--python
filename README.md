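# mmepi

Integrative chromatin analysis of **de novo regulatory activation in
multiple myeloma (MM)**.

Tumor plasma cells rewire their epigenome relative to every stage of
normal B-cell differentiation (naive B cells from blood and tonsil,
germinal-center B cells, memory B cells, tonsillar and bone-marrow
plasma cells). `mmepi` implements the comparative analysis that
isolates myeloma-specific chromatin changes from the (large) changes
that normal differentiation itself produces, for users working with
per-sample peak calls, signal tracks, CpG methylation tables, and
expression matrices across six histone marks, ATAC-seq, WGBS and
RNA-seq.

## What it computes

1. **Stable-baseline differential regions.** For each mark, per-population
   consensus peaks (base-wise voting at fraction ≥ `min_frac`) define a
   baseline: a base is *stably present* when all five normal B-cell
   populations carry it and *stably absent* when none does. Gains in MM
   are bases carried by ≥ `min_mm_frac` of MM samples on stably absent
   ground; losses are stably present bases carried by ≤ 1 − `min_mm_frac`
   of MM samples. Regions are annotated with ATAC overlap fractions,
   group-median CpG β, and host-gene differential expression
   (Welch t on log₂(x+1), BH FDR < 0.05, linear |FC| > 1.5).
2. **Chromatin states.** A deterministic 9-state rule table
   (ActiveProm, WeakProm, BivalentProm, ActiveEnh, WeakEnh,
   Transcription, PolycombRepr, Heterochrom, LowSignal) assigned from
   binary mark presence, majority-voted per group, and summarized as a
   normal→MM transition matrix whose entries are percentages summing
   to 100.
3. **De novo activated regions.** H3K27ac gains with **zero base
   overlap** against every individual normal sample's H3K27ac peaks —
   including bone-marrow plasma cells (bm-PC), the mandatory
   cell-of-origin filter — plus ROSE-style superenhancers: TSS±2 kb
   peaks excluded, constituents stitched at ≤ 12.5 kb, stitched regions
   ranked by mean total H3K27ac signal, and the superenhancer cutoff
   placed where the scaled rank curve is tangent to the slope-1 line.
4. **Target genes.** Each de novo region is linked to the genes in its
   TAD (GM12878-style domains, consumed as given) that are
   up-regulated in MM against *every* normal population with RNA data.
   Adjacent linked genes with correlated expression across MM samples
   (Pearson r > 0.5, p < 0.05, p from t = r√(n−2)/√(1−r²)) chain into
   coregulated groups — pairs, triplets and longer runs.
5. **Motif-anchored methylation.** User-supplied PWMs (MEME minimal
   format) are scanned over region sequences by log-odds on both
   strands; CpGs within hits ± 10 bp are tested for MM hypomethylation
   (group Δβ < −0.25), and composite β profiles are binned around
   motif centers.

Because the corresponding patient datasets are controlled-access, the
package ships a first-class **synthetic data generator**
(`mmepi.simulate`) that emits the full multi-population, multi-assay
dataset with planted ground truth (a JSON manifest) so every stage is
testable end to end.

## Worked example

```bash
mmepi simulate --out dataset --seed 0
# dataset written to dataset (200 planted de novo regions)

printf 'dataset_dir: dataset\nout_dir: results\n' > run.yaml
mmepi run --config run.yaml
```

which prints the per-stage counts (abridged):

```
H3K27ac_gain: 200        # all 200 planted activated regions called
H3K27ac_loss: 19         # 19/20 planted losses survive peak dropout
denovo_regions: 200      # every gain passes the normal/bm-PC zero-overlap filter
superenhancers: 17       # tangent cutoff isolates the high-signal clusters
atac_gain_flagged: 200   # all de novo regions also gain accessibility
target_genes: 162        # genes up in MM vs every normal population, same TAD
coexpression_groups: 40  # 39 pairs + 1 triplet at r>0.5, p<0.05 (41 planted)
hypo_cpg_fraction: 1.0   # motif-flank CpGs hypomethylated in MM (Δβ < −0.25)
transition_matrix_sum: 100.0
```

Interpretation: the pipeline recovered every planted de novo region
with no false positives, linked them to 162 distinct up-regulated
target genes inside their TADs, recovered 40 of the 41 planted
coexpressed adjacent-gene groups (one pair fluctuated below r = 0.5 at
n = 37), and found the planted motif-centered hypomethylation in MM.
Full outputs (BED/TSV per stage plus `report.json`) land under
`results/`. Single stages re-run against a populated results directory,
e.g. `mmepi link --config run.yaml`.

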