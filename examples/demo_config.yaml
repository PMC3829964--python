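# Small end-to-end demo: two worker subcastes, a 40-gene OR set among
# 160 background contigs, one spiked trail-pheromone-receptor candidate.
simulate:
  n_contigs: 200
  n_or_contigs: 40
  frac_known_orf: 0.6
  groups:
    - {name: large, dataset: 2, n_biological: 4}
    - {name: tiny, dataset: 2, n_biological: 4}
  baseline_log2_mean: 9.0
  baseline_log2_sd: 1.5
  class_baseline:
    or_contig: [8.0, 0.5]
  probe_offset_sd: 0.25
  replicate_noise_sd: 0.25
  spikes:
    - {contig: c00000, group: large, log2fc: 1.07}
  fixed_baselines:
    - {contig: c00000, value: 8.8}
thresholds: {min_mean_intensity: 100, min_fold: 2.0, alpha: 0.05}
presence_threshold: 100
ef: {ef_min: 2.0, band_halfwidth: 0.5, log_base: 2, log_offset: 1.0}
de_comparisons:
  - {dataset: 2, groups: [large, tiny]}
ef_comparisons:
  - {focal: large, reference: tiny, gene_set: or_contigs}
go_comparisons:
  - {groups: [large, tiny]}
go: {n_terms: 30, mean_terms_per_contig: 3}
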