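# Methods

This note documents the models, parameter choices and numerical
conventions behind `mmepi`, and what the synthetic benchmark does and
does not demonstrate.

## Coordinate and interval conventions

All coordinates are 0-based half-open, in memory and in BED output;
GTF-lite input (1-based inclusive) is converted at the reader
boundary. Strand is ignored for interval arithmetic — peaks are
unstranded — and gene strand is used only to place the TSS (body start
for `+`, body end − 1 for `−`). Chromosome-name dialects ("chr1" vs
"1") are normalized by an optional style argument at read time. Peak
"presence" in a region means ≥ 1 bp of overlap by default
(configurable `min_bp`). All set operations (merge, intersection,
complement, voting) are implemented as sorted-array sweeps whose
results equal a base-wise boolean-mask formulation; the test suite
enforces this equivalence on random inputs. The genome build is
treated as opaque metadata: nothing in the package depends on a
particular assembly.

## Stable baseline and differential calling

"Stable across normal differentiation" is operationalized base-wise
and strictly: a base is stably present for a mark only if the
consensus of **every** one of the five normal B-cell populations
(pb-NBC, t-NBC, GCBC, MBC, t-PC) covers it, and stably absent only if
none does; bases covered by some but not all populations are unstable
and excluded from both categories. This is the strictest reading of a
stable chromatin profile and makes gains and losses provably disjoint.

Within-population consensus uses base-wise voting at `min_frac = 0.5`
(a base needs half the samples). MM recurrence uses
`min_mm_frac = 0.66`; losses require MM support ≤ 1 − 0.66 rather
than zero so that spurious peaks in single samples do not mask a loss.
Regions shorter than `min_region_bp = 200` are dropped. All three
thresholds are configuration knobs and are echoed into every report,
because studies with unequal per-mark sample counts may need to
harmonize recurrence differently.

Host genes for the annotation panels are assigned by the region
midpoint falling inside a gene body (regions otherwise count as
intergenic); promoter windows play no role here — target-gene
assignment is the linking stage's job and uses TADs instead.

## Chromatin states

A fixed nine-label vocabulary is assigned from binary presence of the
six marks by a precedence cascade (bivalent promoter → active promoter
→ weak promoter → active enhancer → weak enhancer → transcription →
Polycomb → heterochromatin → low signal). The table is total and
deterministic: all 64 presence vectors are enumerated in the tests. A
rule table replaces an HMM-style segmentation deliberately — the
downstream summaries (state distribution, transition matrix) consume
labels, not posterior probabilities, and a deterministic table makes
every downstream number exactly reproducible. The mapping between this
vocabulary and any particular published HMM state model is not
defined. Group states are majorities over samples with ties broken
toward the more active label, which favors detecting activation; the
transition matrix is expressed in percentages of all analyzed regions
and always sums to 100.

## De novo regions and superenhancers

De novo selection filters H3K27ac gain regions against the **union of
individual normal samples' peaks** (any single base of overlap with
any normal sample, including bm-PC, disqualifies), which is stricter
than filtering against population consensuses: "no activation anywhere
in normal differentiation" is read as absolute. bm-PC is a mandatory
filter because it is the cell of origin's closest normal counterpart;
the override flag exists for datasets that genuinely lack bm-PC but
logs a warning. A second, independent audit pass re-checks the
zero-overlap property on the final call set.

Superenhancer calling follows ROSE conventions since no alternative is
specified by the analysis design: stitch distance 12.5 kb, TSS
exclusion ± 2 kb, ranking by across-sample mean of within-region total
bedGraph signal (no input-track subtraction — control tracks are out
of scope), and the cutoff at the point of the ascending rank curve
(both axes scaled to [0, 1]) where a slope-1 line is tangent from
below, computed as argmin(y − x). For a convex curve this is exactly
the point where the tangent slope reaches 1; for a flat curve the
minimum sits at the last index and nothing is flagged super — the
documented degenerate convention. With fewer than three stitched
regions the inflection is undefined and everything is non-super, with
a warning.

## Target linking and coregulated groups

"Associated transcript levels" is operationalized as: a candidate gene
(TSS in the same TAD as the region midpoint) is linked only when
flagged up-regulated in MM against **every** normal population with
RNA data, at FDR < 0.05 and linear fold change > 1.5 — mirroring the
bm-PC key-filter logic on the expression side. Regions falling in
inter-TAD gaps fall back to a ± 1 Mb TSS window and are flagged. Ties
are not broken: a region may have several targets and a gene may serve
several regions. Correlation between region signal and expression is
*not* additionally required.

Adjacency for coexpression is consecutive-TSS order in the **full**
annotation, so an intervening non-target gene breaks a pair; the
within-target-list alternative is available by flag. Kept pairs
(r > 0.5 and p < 0.05, both strict) merge transitively into maximal
chains, which is what naturally produces pairs plus occasional
triplets. DE here uses a Welch t-test on log₂(x + 1) with pseudocount
1 and Benjamini–Hochberg correction; the fold-change threshold applies
two-sidedly on the linear scale ((mean_b + 1)/(mean_a + 1) > 1.5 or
< 1/1.5). No dispersion-shrinkage DE model is used: every claim made
from the DE output is threshold logic, not effect-size estimation.

## Motif-anchored methylation

Motif occurrence is scanned (discovery is out of scope) with log-odds
against a uniform background by default, both strands, hit threshold
0.8 × the maximum attainable log-odds, N bases scoring −∞. "Within or
close to" a motif is hit interval ± 10 bp — a documented choice, not
an inference. CpGs need coverage ≥ 5 in a sample to contribute
(standard WGBS practice); hypomethylation in MM means the group-mean
difference is below −0.25 (the unsigned variant is a flag). The
composite profile bins CpG offsets from motif centers in 50 bp bins
over ± 2 kb; bins with fewer than 3 contributing CpGs are reported as
NA.

## The synthetic data generator

The generator emulates the statistical structure of a multi-layer
tumor-versus-differentiation design at desk scale: two 10 Mb
chromosomes tiled by 50 kb TADs with 1 kb gaps, 300 genes, and by
default 10 MM + 2-per-population ChIP/ATAC samples, 5 MM + 12 normal
WGBS samples, and 37 MM + 4-per-population RNA samples. Planted
structure:

* **Background peaks** shared by all populations with per-sample
  dropout 0.1 and spurious-peak rate 0.05 — high enough that
  recurrence thresholds matter, low enough not to swamp the signal.
* **200 de novo regions** carrying H3K27ac, H3K4me1 and ATAC peaks in
  ≥ 80 % of MM samples and in no normal sample (hard constraint,
  re-audited after generation), grouped 2–3 per TAD so that several
  regions share a target gene (162 distinct targets from 200 regions,
  echoing the many-to-one region/gene ratio of real data). Target
  genes are ~4-fold up in MM only. Spacer genes occupy the TAD slots
  between region-bearing TADs, so annotation-order adjacency between
  independently regulated targets is broken by construction.
* **Coexpressed groups**: 40 adjacent pairs and one triplet share a
  latent factor across MM expression samples giving generating
  r = 0.7; 20 further TADs carry two adjacent up-regulated genes
  *without* a shared factor — these are the true-negative background
  for the coexpression screen (the MM-only fold change does not induce
  within-MM correlation).
* **Methylation**: CpGs planted inside and beside each motif instance
  at β ≈ 0.85 (normal) vs 0.30 (MM); profile CpGs across ± 2 kb with
  an MM shoulder at β ≈ 0.75 so the center dip is sharp; 20 large
  H3K27me3/H3K9me3 blocks with MM-wide methylation loss
  (0.80 → 0.40) emulating hypomethylation of repressed chromatin;
  Beta-distributed per-sample noise (concentration 80) keeps β in
  [0, 1].
* **State transitions**: planted gains carry no marks in normals
  (LowSignal → ActiveEnh); 20 planted losses keep H3K4me1 everywhere
  but lose H3K27ac in MM (ActiveEnh → WeakEnh).
* A short synthetic consensus motif (TTGACGCA, one CpG) with a sharp
  PWM is planted at each region center; region sequences are random
  with chance occurrences of the consensus scrubbed, and are emitted
  as FASTA named `chrom:start-end` so hits map back to genome
  coordinates.

All randomness flows from one seed through named substreams, so a
fixed seed reproduces the dataset byte for byte.

**What passing these benchmarks shows — and what it does not.** The
planted dataset has clean group structure, independent noise, no
copy-number effects, no fragment-level artifacts, no batch structure,
and peak boundaries that coincide across samples up to ± 50 bp jitter.
Recovery of planted truth therefore validates the *logic* of every
stage (filters, thresholds, set algebra, linking rules) and its
determinism, not the pipeline's robustness to the messiness of real
ChIP-seq/WGBS data; precision/recall near 1.0 here is expected by
design, not a performance claim for patient data.

## Numerical and degenerate-input conventions

* Welch test with both groups constant and equal: p = 1 by convention;
  constant but different: p = 0. All-zero expression rows give p = 1
  and fold change 1.
* Pearson correlation on a constant vector is an error (undefined),
  and pairs hitting it are skipped with a log entry in the
  coexpression screen.
* BH q-values come from the standard step-up; an independent hand
  implementation serves as the test oracle.
* Regions with no CpGs report NA methylation; bins with < 3 CpGs are
  NA; a region on a chromosome absent from a signal track scores 0.
* Transition matrices must sum to 100 within 1e-9 — asserted, not
  renormalized.

## Problem sizes

The default generator scale (2 × 10 Mb, 200 planted regions, ~190
files, ~13 k CpG sites × 17 WGBS samples) was chosen so that a full
generate-plus-pipeline cycle completes in well under a minute and the
whole test suite in about one minute on a single CPU, while still
exercising every recurrence, voting and stitching threshold at
non-trivial sample counts. The pure-null calibration uses 2,000 genes
× 200 replicates (400,000 tests), enough to resolve the nominal 0.05
level to ± 0.001 (binomial SE ≈ 0.0003).

## Known limitations

* Presence/absence framing throughout: no signal-quantitative
  differential testing (fold change on coverage), no input/IgG
  correction, no copy-number-aware normalization.
* The state vocabulary is a fixed rule table; it cannot represent
  mixed or probabilistic states.
* TADs are consumed as given; no Hi-C processing or loop calling.
* Superenhancer ranking depends on bedGraph tracks being on comparable
  scales across samples; no cross-sample normalization is applied.
* The DE stand-in (Welch on log counts) is not a replacement for
  dispersion-modeling methods when effect sizes are near the
  threshold.
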