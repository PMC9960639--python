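# Methods

`scstress` re-implements, as a tested library, the bespoke computational
steps of a full-length single-cell RNA-seq analysis of yeast stress
response: library quality control, saturation analysis, spike-in
calibration, hurdle-model differential expression, regulatory-network
corroboration, and variability-driven gene-module discovery. Because the
original measurements depend on a deposited dataset plus external aligners
and databases, every stage here is validated against synthetic data with
known ground truth, generated by the package's own `synth` module.

## Library quality metrics

Five per-cell metrics are computed from read placements (mapped location
records) and gene models:

* **Complexity** — after drawing a fixed subsample of mapped biological
  reads (10⁶ by default; all reads when fewer exist, flagged), the fraction
  with distinct (reference, start, strand) positions. PCR over-amplification
  lowers it. Subsampling is without replacement with an explicit seed.
* **Evenness** — the mean coefficient of variation of per-base coverage
  over gene bodies, restricted to the top ⌈n/2⌉ genes by TPM (ties broken
  lexicographically by gene id). The CV uses the population (divide-by-n)
  standard deviation; zero-coverage bases inside the body are included;
  genes with zero mean coverage are excluded from the mean.
* **Gap score** — per gene, the number of maximal runs of ≥ 5 consecutive
  uncovered bases inside the gene body (runs touching either end count);
  reported as the TPM-weighted mean over genes with TPM > 0.
* **Sensitivity** — genes with at least 5 reads.
* **Bio-reads ratio** — biological reads over all reads, including
  spike-in and unmapped.

Two filter presets reflect common batch-specific thresholds for this kind
of two-batch experiment: batch 1 requires sensitivity > 500, complexity
> 0.1, gap score < 0.5 and evenness < 1.5 (all strict); batch 2 requires
more than 10,000 uniquely mapped reads. "Detection rate" in the batch-1
rule is interpreted as the sensitivity metric (≥ 5 reads); a ≥ 1-read
variant is available via `min_reads`.

Spike-in diagnostics follow ERCC conventions: per-cell spike-in rate,
log–log Pearson correlation of observed expression vs known concentration
over detected spikes, and an eligibility flag (rate > 2% and ≥ 8 detected
spikes). The detection limit is estimated by fitting a logistic curve of
detection probability against log10 concentration (pooled over eligible
cells) and reporting the 50%-detection concentration; with perfect
separation the smallest always-detected concentration is returned, and
all-/none-detected tables return below-min / above-max sentinels. The
logistic-midpoint definition is a documented stand-in — the upstream
literature's exact formula is not restated anywhere we could implement
from, so the fit is validated by parameter recovery on simulated data.

## Saturation

Gene-detection saturation is measured by subsampling reads without
replacement at a ladder of sizes (mean over replicates), and at the cell
level by pooling the reads of random k-subsets of cells. At full depth the
curve equals the library's detected-gene count exactly; at k = group size
the pooled curve equals the union of detected genes.

## Quantification and cell structure

TPM divides counts by gene length before per-cell scaling to 10⁶; CPM
scales raw counts. Gene filtering keeps genes detected in ≥ ⌈f·n⌉ cells
(inclusive boundary, f = 0.2 by default). PCA runs on per-gene-centered
log2(TPM+1) without variance scaling (scaling is available but off by
default); component signs are fixed by making each component's
largest-magnitude loading positive. Cell clustering uses complete linkage
on 1 − Pearson correlation of transcriptomes.

## Hurdle differential expression

For each filtered gene, expression on log2(CPM+1) is modeled in two parts,
each adjusted for the standardized cellular detection rate (CDR, the
fraction of test genes detected per cell):

1. a logistic model of detection ~ group + CDR;
2. an ordinary-least-squares model of expression among detected cells
   ~ group + CDR.

The group effect is tested by a likelihood-ratio statistic summed over the
two parts against a chi-square with the summed degrees of freedom. Two
numerical choices matter:

* The continuous part's LR is computed as the chi-square deviate equivalent
  to the exact F-test p-value. The raw n·log(RSS ratio) statistic is
  anti-conservative in the far tail at a few dozen cells, which matters
  when 2,000 genes are tested; the F-based transform is exactly calibrated
  under Gaussian errors and keeps the summed-chi-square framework.
* The logistic part carries a tiny ridge penalty (10⁻³) on the
  non-intercept coefficients, and the Newton solver is damped (step halving
  until the penalized likelihood improves). This keeps (quasi-)separated
  genes — common when a gene is detected in all but one cell — finite,
  convergent, and exactly symmetric under swapping the group labels.

Degenerate parts are dropped with the df reduced accordingly: the logistic
part when detection is constant across cells, the continuous part when
fewer than 3 cells per group are detected. The reported log2FC is the
difference of group means of log2(CPM+1) over **all** cells (zeros
included), which is symmetric and matches the scale used for heatmaps. No
shrinkage is applied to either part.

DEGs are called at FDR < 0.05 (Benjamini–Hochberg) and |log2FC| > 0.5, both
strict. The 0.5 threshold is configurable; a linear fold-change variant
(> 1.2) is expressible through the same parameter.

## TF–target permutation test

For a TF with N predicted targets, the statistic S is the mean absolute
correlation (Spearman by default, Pearson optional) between the TF's
expression and each target. The null distribution is built from M (default
10,000) random draws of N genes from the expression universe excluding the
TF itself, each scored the same way; the empirical p-value is
(1 + #{null ≥ S}) / (M + 1). The pseudocount avoids reporting an exact
zero from a finite sample; with maximally correlated targets the smallest
attainable p is 1/(M+1) ≈ 10⁻⁴. Using the *absolute* correlation for both
the observed and null statistic is the only internally consistent reading
of the procedure's description; a signed variant is available. Across TFs,
raw and BH-adjusted p-values are both reported, since no single
multiplicity convention is canonical here.

## Gene modules and TF assignment

Within one (condition, batch) stratum, genes detected in ≥ 10% of cells are
clustered on the distance 1 − |Pearson r| with Ward linkage (the 'ward.D2'
convention — the squared-dissimilarity update applied to the supplied,
non-Euclidean distance). The number of clusters maximizes the mean
silhouette over a candidate range (2–200 by default, ties toward smaller
k); when even the best silhouette is below 0.1 the partition is flagged as
weak structure and the smallest k is returned. Mean silhouette is a
deliberate, recorded stand-in for the NbClust index battery (~30 indices
with majority voting), which is out of scope; the method tag in the output
makes the substitution visible. Each cluster is assigned the most enriched
TF from a curated interaction table by an upper-tail hypergeometric test,
BH-adjusted across TFs within the cluster, only when the adjusted p is
below 0.05; exact ties break by TF id and are recorded.

## The synthetic-data generator

The generator emulates the *structure* of full-length yeast scRNA-seq data,
not its content:

* **Gene models** — non-overlapping genes on linear references, lengths
  uniform in 400–1,000 bp, intergenic gaps drawn from a mixture of short
  (50–900 bp) and long (1.1–3 kb) spacings so promoter extraction meets
  both regimes, random strands.
* **Read placements** — per-cell depth Poisson(90,000), of which ~60% are
  biological (10% spike-in, 30% unmapped, mirroring the mapping-rate
  regime of this protocol class). Biological reads pick a gene
  proportionally to a lognormal expression profile (ln-sd 2.0: a few genes
  dominate, as in real transcriptomes) and a start position within the
  gene body with density ∝ exp(b·x), x the relative position from the 5'
  end (b = 0.4 by default), emulating oligo-dT 3'-end bias; reads may run
  past the annotated 3' end as clipped alignments do. A fraction (0.15) of
  reads are exact PCR copies of already-placed reads. Low-quality cells get
  half depth and doubled duplication.
* **Counts** — Gamma–Poisson (negative binomial, dispersion 0.3) around
  the shared expression profile, with logistic dropout on ln(mean),
  per-(gene, batch) lognormal offsets, and planted log2 fold-changes
  (random sign) in non-reference conditions. The count model is the
  standard scRNA-seq noise model; the study this emulates specifies none.
* **Spike-ins** — 92 spikes spanning 20 doublings of concentration;
  observations are lognormal around a value proportional to concentration
  (ln-sd 0.5 by default).
* **TF modules** — member genes share a latent per-cell factor giving
  pairwise correlation ρ; the TF's own transcript carries the same factor.
  Values are emitted directly on the log2(TPM+1) scale.

Depth, read length (250 bp), gene count (1,000) and the expression ln-sd
were fixed together, once, by first-principles calibration so that the
default study realizes the regimes the filters assume: healthy cells sit a
comfortable margin above the 500-gene sensitivity threshold while
half-depth cells fall clearly below it, and the TPM-weight of the gap score
is carried by genes covered deeply enough that healthy cells stay under
0.5. With ~60% of 90,000 reads biological, the median gene receives ~10–50
reads — a deliberately down-scaled analogue of the ~9.5 M reads/cell of a
real study, keeping the full test battery runnable in minutes on one CPU.

What the generator does **not** emulate: real yeast sequence content (the
genome is random nucleotides), UMI structure, fragment-length variation,
positional sequence biases beyond the single exponential trend, ambient
RNA, doublets, or empirically matched per-condition variance. Tests passing
on this generator demonstrate the correctness and calibration of the
*procedures*, not biological conclusions about any real dataset.

## Problem sizes used by the test battery

Oracle-equivalence checks run 50 random miniature libraries (12 genes,
~300 reads). Filter recovery uses the default study at 40 cells with 30%
planted low-quality cells. DE calibration uses 2,000 genes and 20+20 cells
(10–20 null replicates; power on 5% planted |log2FC| = 2 genes).
Permutation validity uses 100–200 independent TFs at M = 10,000 and 50–100
planted-module replicates (ρ = 0.8, 20 targets, 50 cells). Module recovery
uses 10 planted modules × 20 genes over 60 cells. These sizes are the
package's reference configurations and are reproduced by
`scripts/acceptance.py`.

## Known limitations

* The hurdle test relies on asymptotic chi-square calibration for the
  logistic part; at very small groups (< 10 cells) it can be mildly
  conservative.
* The BH procedure is not idempotent in general (re-adjusting an already
  adjusted vector can change it); adjusted p-values should be computed once
  from raw p-values.
* `detection_limit` pools cells rather than fitting per-cell curves;
  per-cell limits would need many spikes per concentration.
* Ward on a non-Euclidean dissimilarity is a convention, not a guarantee
  of objective-function optimality.
* BAM ingestion is not implemented; placements are consumed as TSV (the
  reference dialect) or coverage as bedGraph.
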