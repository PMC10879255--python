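# Methods

This note documents the models, parameter choices and numerical conventions
behind `methgroup`, and what the synthetic benchmark does and does not
establish about real data.

## Input model and conventions

All genomic coordinates are 0-based half-open internally; the coverage
reader converts from 1-based bismark-coverage positions (or accepts 0-based
bedGraph via `--format bedgraph`) at the boundary.  A CpG observation is a
strand-collapsed single position with methylated/total read counts; beta is
recomputed from counts when coverage is positive, so the fraction column of
the input is never trusted beyond validation.  Sites below `min_coverage`
(default 5 reads) are *masked*: excluded from feature matrices and HMR
seeding, but their read counts still contribute to CNV bin coverage — a
noisy beta is uninformative, the reads underneath it are not.

## Synthetic cohort generator

The generator emulates a small tumor WGBS + RNA-seq study so that every
downstream stage has a planted truth to be scored against.  Default
conditions: 30 samples in three latent groups (proportions 0.40/0.35/0.25,
apportioned by largest remainder → 12/10/8), two 10 Mb chromosomes, 20,000
CpGs, 200 regularly spaced 1 kb islands, Poisson depth with mean 30.

* **Methylation.**  Per-site baseline beta ~ Beta(8, 2) in open sea
  (high, mean 0.8) and Beta(1.5, 8) inside islands (low), matching the
  canonical genome-wide methylation landscape.  Each group owns planted
  hypomethylated blocks (150 per group; 300 for group 2, the HMR-enriched
  group) of 8–20 consecutive CpGs with beta ~ Beta(1, 9).  Blocks are
  carved from CpG streaks whose inter-site gaps are ≤ 400 bp — 60% of CpGs
  live within ±4 kb of an island, so these dense streaks exist mostly in
  island flanks.  This placement rule is a generator design choice: a
  planted block is only a meaningful recovery target if a gap-bounded
  segmenter (max gap 500 bp) can in principle traverse it.  Blocks never
  share a CpG across groups and are separated by at least one buffer site.
* **Sequencing.**  Depth per site ~ Poisson(30 × CNV multiplier),
  methylated reads ~ Binomial(depth, beta).  Planted CNVs are arm-level
  (half of a chromosome per group, multiplier 0.5 or 1.5) — the typical
  scale of copy-number change in meningioma-like tumors, and a scale the
  binned segmenter (min 5 bins per side) can delineate exactly.
* **Expression.**  Counts ~ NegativeBinomial(μ, dispersion 0.1) with
  lognormal baseline means; 200 planted DE genes per group (half up, half
  down at |log2FC| = 2) plus three proliferation-marker namesakes (MKI67,
  TOP2A, FOXM1; synthetic genes, not real annotations) up-shifted by
  log2FC 2.4 in group 2.
* **Metadata.**  Mitotic index ~ Poisson(6) in group 2 vs Poisson(1)
  elsewhere; P(WHO grade ≥ 2) = 0.8 in group 2 vs 0.15 elsewhere.

What the generator does **not** model: per-sample correlated biological
variability (within a group, samples differ only by counting noise), GC or
mappability structure in coverage, strand-resolved CpGs, read-level error,
library-size variation in RNA counts, or realistic gene annotation.
Consequently, passing recovery tests demonstrates that the estimators are
correct and well-calibrated under their stated noise model — not that their
defaults are tuned for the messier variance structure of real cohorts.

**Seeding.**  One master seed; each stage draws from a child stream derived
via `SeedSequence(master, spawn_key=(stage_offset,))` with fixed, documented
offsets, so re-running a single stage from files reproduces the monolithic
run bit for bit.

## Group discovery

Features are the 5,000 highest-variance CpGs (ties broken by genomic
order) among sites unmasked in every sample.  Variance ranking is the field
default when no supervised signal is available.

k-means is Lloyd's algorithm, squared-Euclidean objective, best of
`n_restarts` initializations (k distinct rows), with empty clusters
repaired by reassigning the point farthest from its current center.  When
features outnumber samples, distances are computed in an exact isometric
row embedding obtained from the eigendecomposition of the centered Gram
matrix; this changes labels and dispersions only at float round-off and
makes the resampling loops fast at WGBS dimensionality.

Consensus clustering uses H = 100 subsamples at fraction p = 0.8
(Monti-style defaults).  Sample pairs never drawn together receive the
neutral consensus 0.5 with a logged warning; at the defaults this is
vanishingly rare.  The CDF area is integrated over the sorted distinct
consensus values, A(k) = Σ (x_i − x_{i−1})·CDF(x_{i−1}); Δ at the smallest
k equals A there.

The gap statistic uses a featurewise uniform-box null (B = 50) and the
one-standard-error rule.  **It is computed on the top 10 principal-
component scores of the feature matrix, not on the raw 5,000 features.**
On thousands of features the uniform reference's marginal dispersion gain
per added cluster scales like 1/dimension while its Monte-Carlo spread s_k
shrinks with feature averaging, so Gap(k) rises monotonically past the true
k and the stopping rule degenerates to argmax.  Any k ≤ 6 cluster structure
lives in ≤ 5 principal axes; on score matrices the reference retains a
meaningful per-cluster gain and the rule stops where dispersion stops
improving.  The selection is insensitive to the exact number of components
(5, 10 and 20 give identical selections on the default cohort); 10 is kept
as a round default with headroom.  `gap_statistic(..., n_pcs=None)` gives
the raw-feature form.

`select_k` combines the two: the primary decision is the gap rule
re-applied over k ≥ 2; the corroborating Δ-area elbow is the largest k ≥ 3
with Δ(k) ≥ 0.1 (else the smallest k scanned).  Discordance is flagged in
the diagnostics, never fatal — the gap decision wins, since it carries an
explicit null model.  Δ(4) sits near the 0.1 threshold on the default
cohort, so the concordance flag can flicker across seeds while the selected
k stays 3.  Final labels come from k-means with 50 restarts on the full
feature matrix, groups renumbered by descending size (ties by smallest
member index).

Hierarchical clustering is Ward on Euclidean distances — the linkage whose
objective matches k-means.  PCA is an in-repo SVD with a deterministic sign
convention; UMAP (default, 15 neighbors) and t-SNE delegate to umap-learn
and scikit-learn behind the same contract.

## HMRs, context and CNVs

The HMR caller is a deliberately transparent threshold-merge segmenter
(beta < 0.3 at coverage ≥ 5; successive hypomethylated sites merge while
gaps ≤ 500 bp; candidates keep ≥ 4 CpGs), chosen over HMM-based callers for
testability.  Intervening methylated sites do not break a run; only the
spacing of the hypomethylated sites does.  Segment bounds span first to
last+1 member positions; mean beta is unweighted over member sites.

Context geometry: shores are the ±2,000 bp island flanks, shelves the next
±2,000 bp, precedence island > shore > shelf, everything clipped to
chromosome bounds; the four classes partition each chromosome exactly.
An HMR's context is the label of maximal base overlap (ties resolved by
precedence); because "island or shore" summaries are often quoted as
any-overlap, the summary reports both the maximal-overlap fraction and an
any-overlap variant.  Elements use precedence promoter > exon > intron >
intergenic with promoter = [TSS − 2000, TSS + 500) on the gene's strand;
without an exon track, gene bodies count as intron.

CNVs: coverage (all reads, masked sites included) summed in 500 kb bins;
per-sample bin ratios r = cov / median(cov over bins); log2 ratio against
the per-bin cohort median of r.  Bins with zero cohort median are masked
with a warning.  Each chromosome is segmented by recursive binary
splitting: the split maximizing Welch's |t| between left/right bin means is
accepted when |t| > 4 and both sides keep ≥ 5 bins.  Calls use
|mean log2 ratio| ≥ 0.3.  Known consequences of these choices: events whose
boundaries are not expressible with ≥ 5 bins on both sides are absorbed or
diluted, and the per-sample median normalization biases ratios slightly
when an event covers a large fraction of the genome.  GC correction is
omitted (the generator produces no GC structure) — a documented limitation
for real data.

## Expression and cohort statistics

TPM is the usual length-normalized rate scaled to 1e6 per sample.
Differential expression is a two-sided Welch t-test on log2(TPM + 1), one
group vs the rest; genes are significant at |log2FC| > 1 and raw p < 0.05,
with BH q reported alongside (the significance rule deliberately uses raw
p to match the thresholding convention of volcano displays; q is exposed
for stricter use).  Degenerate genes (zero variance on both sides) get
p = 1 at equal means.  Enrichment is the one-sided hypergeometric upper
tail over a universe fixed to all genes in the count matrix, BH-corrected
across sets.

Cohort contrasts use the pooled-variance Student t (not Welch) with exact
t-distribution p-values — the convention of clinical cohort tables — and
apply it even to the binary high-grade indicator.  A t-test on a 0/1
indicator is anti-conservative relative to Fisher's exact test at these
sample sizes; it is kept because it mirrors how such tables are commonly
reported, and the caveat is attached here rather than silently substituted.

## Numerical choices and degenerate inputs

* Feature selection errors on < 10 usable sites or all-zero variance;
  requesting more features than exist warns and uses all.
* Consensus requires H ≥ 2 and n ≥ max(k)+1; CDF areas need a contiguous
  k range.
* Gap dispersion uses the within-cluster SS; the pairwise form
  Σ_r (1/2n_r) Σ d² is kept as an independent implementation and asserted
  equal to 1e-9 in tests.
* Zero pooled variance: t = 0, p = 1 at equal means; p = 0 with a warning
  otherwise.
* Largest-remainder ties go to the group with the smaller integer quota,
  then the higher index — deterministic and sum-exact.
* All tie-breaks (feature ranking, group renumbering, context precedence)
  are deterministic, so identical configs and seeds give byte-identical
  outputs.

## Problem sizes

Tests and the reproduction script run the full default cohort (30 × 20,000
CpGs, 5,000 genes) where a claim concerns the default conditions — group
number and label recovery over ten master seeds, HMR/CNV recovery,
calibration with ≥ 1,000 null tests — and scaled-down cohorts (18 samples,
4,000 CpGs, same densities and effect sizes) for unit-level contracts.
These sizes are the package's chosen benchmark conditions; the algorithms
have no intrinsic size limits beyond memory.

## Known limitations

Binomial/NB noise only (no biological within-group variance); no GC/
mappability correction; promoter and flank widths are fixed conventions;
the HMR caller has no background model (it thresholds absolute beta); the
combined k-selection is a declared convention, not an inferential
procedure; enrichment assumes an unbiased universe and independence across
sets.
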