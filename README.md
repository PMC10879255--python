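# methgroup

Unsupervised discovery and characterization of DNA-methylation groups in
small whole-genome bisulfite sequencing (WGBS) tumor cohorts — the kind of
multi-stage analysis used to establish molecular groups of tumors such as
meningiomas, where ~30 samples with paired RNA-seq must be partitioned into
stable epigenetic groups and each group profiled for hypomethylated regions
(HMRs), copy-number changes, expression programs and clinical correlates.

The package provides, as a tested library plus a `methgroup` command-line
pipeline:

* **Group discovery** — consensus k-means over subsampling resamples
  (Monti-style), summarized by the consensus CDF area A(k) and its relative
  change Δ(k); the gap statistic with a Monte-Carlo uniform null and the
  one-standard-error rule; Ward hierarchical clustering; PCA / UMAP / t-SNE
  embeddings; and a combined k-selection with final group assignment.
* **Methylome features** — a threshold-merge HMR segmenter, CpG
  island/shore/shelf context annotation (±2 kb flank geometry), genomic
  element annotation, and CNV segmentation from binned read coverage with
  recursive binary splitting on Welch's t.
* **Expression analysis** — TPM normalization, per-group one-vs-rest
  differential expression on log2(TPM+1) with the |log2FC| > 1, p < 0.05
  rule, volcano classification, and hypergeometric gene-set
  over-representation with Benjamini–Hochberg correction.
* **Cohort statistics** — pooled-variance Student t contrasts of mitotic
  index, marker expression and high-grade membership for a group of
  interest.
* **A synthetic cohort generator** that plants the assumed structure
  (three latent groups, group-specific hypomethylated blocks with one
  HMR-enriched group, arm-level coverage CNVs, negative-binomial expression
  with planted markers, grade/mitotic-index skew) and records every planted
  feature in a truth ledger, so the whole pipeline is scoreable end to end.

## The statistics at the core

For a samples × features beta-value matrix (top-variance CpGs), consensus
clustering draws H = 100 subsamples of fraction p = 0.8, k-means-partitions
each, and records for every sample pair the co-clustering rate
C_k(i,j) = Σ_h M_h(i,j) / Σ_h I_h(i) I_h(j).  The empirical CDF of the
upper-triangle entries of C_k yields the area A(k) and
Δ(k) = (A(k) − A(k−1)) / A(k−1); a stable k shows near-binary consensus and
an elbow in Δ.

The gap statistic compares the log within-cluster dispersion
W_k = Σ_r (1/2n_r) Σ_{i,j∈C_r} d²(i,j) (≡ within-cluster sum of squares)
against B = 50 reference datasets drawn uniformly over each feature's
observed range: Gap(k) = (1/B) Σ_b log W*_kb − log W_k, with
s_k = sd_b(log W*_kb)·√(1+1/B), choosing the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}.  The statistic is computed on the top
principal-component scores of the feature matrix (default 10), where the
uniform reference retains a meaningful per-cluster dispersion gain (see
`docs/methods.md`).

HMRs are maximal runs of ≥ 4 CpGs with beta < 0.3 at coverage ≥ 5 and
inter-site gaps ≤ 500 bp; context is assigned by maximal base overlap with
islands, their ±2 kb shores, the next ±2 kb shelves, or open sea.  CNV log2
ratios are per-sample median-normalized binned coverages scaled against the
per-bin cohort median.  Enrichment p-values are the hypergeometric upper
tail P(X ≥ o) for an overlap o between a significant-gene query and a gene
set within a fixed universe.

## Worked example

The packaged default configuration simulates a 30-sample cohort (three
groups of 12/10/8 samples, 20,000 CpGs on two 10 Mb chromosomes, depth 30×,
5,000 genes) and runs every stage:

```bash
methgroup run --out results_demo --seed 7
```

`results_demo/cluster_summary.json` reports the group discovery outcome:

```json
{"k_selected": 3, "k_gap": 3, "k_delta": 3, "concordant": true, "ari_vs_truth": 1.0}
```

Three methylation groups are selected (gap statistic and Δ-area elbow both
at k = 3) and the final assignment reproduces the planted partition exactly
(adjusted Rand index 1.0).  The per-k diagnostics table shows the decision:
Gap jumps from −0.43 at k = 2 to 2.73 at k = 3 and declines after
(2.46 at k = 4), while Δ(k) collapses from 0.48 at k = 3 to 0.11 at k = 4.

Downstream, the HMR-enriched group carries more hypomethylated regions than
the others (mean 329 HMRs/sample vs 260; ~75% of HMRs in island or shore
context), each group carries one arm-level CNV covering 25% of the genome,
and the per-group volcano tables flag ≈ 400 significant genes each, with
the planted up-programs as the top-enriched gene sets (q < 1e-6).
`comparisons.tsv` summarizes the proliferative group's contrasts
(group mean vs rest mean, pooled-t, df = 28):

```
variable        mean_group  mean_rest   t        p
MKI67             246.7       53.9      9.83     < 1e-6
TOP2A            1221.6      223.3     11.35     < 1e-6
FOXM1             360.7       78.3     13.18     < 1e-6
mitotic_index       5.1        1.2      6.99     < 1e-6
high_grade          1.0        0.2      6.11     < 1e-6
```

Each stage can also be run separately (`methgroup simulate`, `cluster`,
`hmr`, `cnv`, `de`, `enrich`, `stats`, `report`) against the files of a
previous stage; `report` assembles `report.json` / `report.md` from
whatever results are present.

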