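# Methods

## Scope and data model

The package implements the post-peak-calling analysis stack for a
two-group (control vs centenarian), two-sex bulk ATAC-seq + RNA-seq cohort.
Inputs are plain text: per-sample scored peak intervals (broadPeak, q-value
as −log10 in column 9), feature × sample integer count matrices (TSV), a
sample sheet (sample_id, group, sex, optional library sizes), per-cell-type
chromatin-state segmentations (BED4), a blacklist (BED), a TSS table
(BED6), gene bodies (BED6), peak sequences (FASTA) and JASPAR-style count
matrices.  All intervals are 0-based half-open.  Alignment, peak calling
and read counting are upstream of this package.

## Consensus peak set

Peaks with q ≤ `q_max` (default 0.01) from every sample are pooled; the
union is merged with book-ended intervals coalescing (the behaviour of
standard merge tools).  Filters are conjunctive and order-independent:

* support: max over samples of the raw fragment count must be **strictly
  greater** than `min_reads` = 20 ("more than 20 reads");
* artifact ceiling: max over samples of CPM (count × 10⁶ / library size)
  must **not exceed** `max_cpm` = 500 (inclusive);
* blacklist: any ≥ 1 bp overlap excludes;
* autosomes: chromosome must be in the configured set (default chr1–chr22,
  "chr"-prefixed names).

The support filter uses raw counts: the quantity named in the rule is a
read count, and per-sample normalization is handled separately by the CPM
ceiling.  Library sizes for CPM are the per-sample sequencing totals
supplied with the sample sheet; column sums of the count matrix are only a
fallback, since in real ATAC libraries most fragments fall outside peaks.

## Differential engine

Counts are modeled as NB(μ, α) with Var = μ + αμ², log link,
log μ = log s + β₀ + β_g·group + β_s·sex.  Components:

* **Size factors** — median-of-ratios to the geometric-mean
  pseudo-reference over all-positive features; library-size ratios as a
  warned fallback when no feature is all-positive; a single sample gets 1.
* **Dispersion** — per-feature method of moments on normalized counts:
  within each design cell (group × sex, or group only for single-sex
  subsets) α̂_c = (s² − m̄)/m̄²; cells pooled weighting by degrees of
  freedom; floored at 10⁻⁸.  No empirical-Bayes shrinkage and no trend
  fitting — the estimator is transparent and testable against closed
  forms, at the cost of per-feature noise (see Limitations).
* **Fit** — IRLS with α held fixed, batched across features (the working
  weight is μ/(1 + αμ); the normal equations are solved feature-wise with
  a 10⁻¹⁰ ridge for numerical safety; linear predictors are clipped to
  ±30).  Convergence is a 10⁻¹⁰ sup-norm change in β; non-converged or
  all-zero features report p = NA.
* **Inference** — Wald z = β_g/se(β_g) against the normal reference;
  log2fc = β_g/ln 2; Benjamini–Hochberg step-up across features (NA
  excluded from m and propagated).  Calls: opening/up if padj < 0.05 and
  log2fc > log2(1.5); closing/down if padj < 0.05 and log2fc < −log2(1.5);
  both inequalities strict, the fold-change threshold interpreted on the
  raw (unshrunken) estimate.

Sex-stratified contrasts ("female", "male") are the same engine on the
subset sample sheet with a group-only design; the "all" contrast includes
the sex covariate.

## Annotation

States overlapping a peak by ≥ 1 bp are collected per cell type and
resolved to the single highest-priority state under the fixed total order
(Active Enhancer first, Quiescent/Low signal last).  The full peak, not
the summit, is intersected; the summit (midpoint when absent) is used only
for positional annotation.  Peaks with no overlapping segment — including
chromosomes absent from a segmentation — default to "Quiescent/Low
signal", i.e. "no functional annotation".  Meta-state pooling is a total
map onto 6 categories; "Genic Enhancer" joins Enhancer and "TSS Flanking"
joins TSS, following Roadmap naming conventions (both overridable, since
reference state vocabularies differ between projects).  A peak is
cell-specific when its resolved state is in the active set (default:
Active Enhancer, Genic Enhancer, TSS Flanking, plus "Active TSS" when the
vocabulary defines it; bivalent and weak states deliberately excluded) in
exactly one cell type.  Positional categories: promoter when the summit is
within ±2,000 bp of any TSS (inclusive), else genic on ≥ 1 bp gene-body
overlap, else intergenic.

## Integration

Promoter pairing emits a pair for every (peak, TSS) whose half-open
window [tss − 1000, tss + 1000) overlaps the peak by ≥ 1 bp; one peak may
pair with several genes.  Distances are TSS-relative and strand-aware:
the signed distance from the TSS to the nearest peak edge (0 when the peak
covers the TSS), negated on the minus strand, so negative means upstream
in transcript orientation.  Nearest-gene assignment minimizes
|TSS − peak midpoint| on the same chromosome, labels the pair proximal
when the midpoint falls in the gene's strand-aware basal window (5 kb
upstream / 1 kb downstream) and distal otherwise, and returns nothing
beyond 1,000 kb.  Correlation deduplicates pairs by (peak, gene) — with an
option to collapse to the nearest pair per gene — and reports Pearson r
with the regression-slope t-test p (NA below n = 3).

## Motifs and TF nomination

PWM: log2(((count + pseudocount)/column sum) / background), default
pseudocount 0.25 and uniform background.  Scanning slides both strands
(the reverse strand scores each window's reverse complement), reports
windows at or above the threshold — default 80% of the PWM's maximum score
— and skips windows containing non-ACGT bases.  Enrichment: a peak "has"
the motif when ≥ 1 hit lies in its summit ± 200 bp window; the p-value is
the one-sided hypergeometric upper tail of the foreground overlap drawn
from the pooled foreground + background universe, with BH across motifs.
The background is the matched universe of non-differential consensus
peaks, replacing discovery-tool ZOOPS binomials with an exact,
dependency-free test of the same monotone behaviour.  Occurrence profiles
bin hit centers in 10-bp bins over summit ± 500 bp and report the fraction
of peaks with ≥ 1 hit per bin.  The aggregate footprint averages per-bp
insertion vectors aligned on motif centers; depth = mean(flank) −
mean(core) (flank 50 bp), positive depth indicating protection.  This is a
deliberately simple aggregate summary, not a bias-corrected footprint
model.

Nomination intersects motif enrichment with the TF's own differential
expression: per stratum, opening+up requires motif padj < 0.05 in opening
peaks and the TF gene called up (symmetrically closing+down); the report
lists the supporting strata.  TF→gene identity is an explicit input table —
no fuzzy name matching.  Target genes are the nearest genes of
motif-bearing differential peaks (promoter-restricted assignment available
via the pairing rule), joined with their expression calls.

## Gene-set enrichment

One-sided hypergeometric upper tail per term against a user-supplied
universe, with Bonferroni–Holm step-down (the default, matching the
figure-legend convention of grouped GO enrichment) or BH.  Term databases
are plain GMT files; no live ontology downloads.  The category resolver
collapses multiple functional annotations per gene to the single
highest-priority category (immunity > metabolic > transcription,
translation > migration > mitochondria > axon > development); genes with
no category are "unclassified", genes with only unlisted categories
"other".

## Synthetic cohort generator

The generator emulates the study's statistical structure, not its genome:

* **Cohort** — 15 control vs 15 centenarian samples by default, sex ratio
  0.65 female (the real cohort is roughly two-thirds women); library sizes
  log-uniform on [1.5×10⁷, 3×10⁷].
* **Genome skeleton** — five 3-Mb autosomes plus a 1-Mb chrX decoy that
  exercises the autosome filter; 5,000 non-overlapping peaks of 300–700 bp
  placed in per-chromosome slots; ~1% of effect-free autosomal peaks are
  blanketed by blacklist intervals.
* **Effects** — 10% opening and 5% closing peaks at |log2fc| = 1.5,
  planted on autosomes only; 20% of planted effects are female-only,
  implemented as a group × sex interaction on the NB mean (a miniature of
  the female-dominant differential landscape).  Counts are gamma-Poisson
  (NB) with dispersion α = 0.2 around baseline × size factor ×
  2^(lfc·group).  Baselines are log-normal (median 50 ATAC, 100 RNA).
* **Genes** — 2,000 genes whose TSSs sit at the summits of a random subset
  of autosomal peaks; each gene inherits its host peak's effect with
  N(0, 0.3) log2 noise, so accessibility and expression changes are
  congruent by construction.
* **Planted TF** — one gene is designated the longevity TF ("ERG" by
  default, with an ETS-family-like consensus ACAGGAAGTG): its motif is
  planted near the summit of opening peaks with probability 0.4 (0.05
  anywhere in other peaks), and its own transcript is strongly induced
  (log2fc 2.5 from a +1-sd baseline — the emulated regulator goes from
  near-absent to clearly expressed, so its detection reflects the
  pipeline, not borderline sampling noise).  A decoy motif (GCGCATGCGC)
  ships with a gene mapping but is never planted above chance.
* **Peak calls** — every sample emits every true peak with boundaries
  jittered by rounded N(0, 10 bp) noise and a q-score that passes the 1%
  cutoff with probability 0.95 independently per peak and sample; with
  ≥ 10 samples every true peak passes somewhere with probability ≈ 1.
* **States** — per cell type (default: plasma cell, naive B cell,
  monocyte) the segmentation tiles each chromosome: around each peak one
  of four patterns (cell-specific active 10%, shared active 10%,
  non-active regulatory 15%, quiescent 65%), quiescent elsewhere.
* **Determinism** — one cohort seed; per-stage generators derived by
  CRC-hashing stage names into a SeedSequence, so outputs are
  byte-identical for a fixed seed regardless of call order.

What the generator does **not** emulate: real sequence composition and
mappability, fragment-length structure, peak-width/GC biases, correlated
(batch) noise, cell-type mixture deconvolution, and realistic gene
density.  Passing recovery tests therefore demonstrates the correctness
and calibration of the statistical machinery under the stated generating
model, not performance on real libraries.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: the full 2,047-subset
priority oracle; a five-peak filter fixture with one rule violation each;
a 2,000-feature 10 vs 10 null cohort at α = 0.2 for type-I calibration of
the Wald test at the generating dispersion; the default 5,000-peak 15 vs 15
cohort for planted-effect recovery; exhaustive hypergeometric enumeration
for all universes ≤ 12 and 10⁴-entry correction vectors; 1,000 pairs at a
generating r of 0.6 for correlation recovery; and 20 seeds of a 2,500-peak
/ 1,000-gene cohort for the end-to-end nomination rate — sizes chosen so
the whole battery completes in a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

* The plug-in method-of-moments dispersion makes the full pipeline's Wald
  test modestly anticonservative at small n (empirically ~7% raw p < 0.05
  under the null at 10 vs 10, vs ~5% when the dispersion is known):
  estimation noise in α̂ correlates with the test statistic.  Shrinkage
  estimators fix this at the cost of opacity; the engine trades a little
  calibration for transparency, and the calibration test pins the fixed-α
  behaviour.
* No independent filtering, outlier replacement or fold-change shrinkage;
  thresholds apply to raw estimates.
* The footprint summary is descriptive; it does not correct enzyme
  sequence bias.
* Single-TSS genes; no isoform-aware promoter definitions.
* The hypergeometric motif test treats peaks as exchangeable; it does not
  match foreground and background on GC or width beyond using the same
  consensus-peak universe.
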