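# Default pipeline configuration: synthetic cohort emulating a ~30-sample
# WGBS + RNA tumor study with three planted methylation groups.
seed: 7
inputs: synthetic
coverage_format: bismark
output_dir: methgroup_results
synthetic:
  n_samples: 30
  group_proportions: [0.40, 0.35, 0.25]
  n_chroms: 2
  chrom_length_bp: 10000000
  n_cpgs: 20000
  n_islands: 200
  island_width_bp: 1000
  depth_mean: 30.0
  blocks_per_group: [150, 300, 150]
  hmr_group: 2
  n_genes: 5000
  nb_dispersion: 0.1
  de_genes_per_group: 200
  de_log2fc: 2.0
  mitotic_index_means: [1.0, 6.0, 1.0]
  high_grade_prob: [0.15, 0.80, 0.15]
clustering:
  k_min: 2
  k_max: 6
  gap_k_min: 1
  H: 100
  p: 0.8
  B: 50
  n_top: 5000
  n_restarts: 20
  gap_n_pcs: 10
  embedding: umap
  n_neighbors: 15
hmr:
  tau: 0.3
  max_gap: 500
  min_cpgs: 4
  min_cov: 5
cnv:
  bin_size: 500000
  t_threshold: 4.0
  min_bins: 5
  call_cutoff: 0.3
de:
  fc_threshold: 1.0
  p_threshold: 0.05
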