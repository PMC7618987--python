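# Demo pipeline configuration: all eight packaged supercluster programs,
# study-style fold change 8 over a 0.5-count baseline, full stage set.
seed: 1
min_features: 50
simulate:
  species: human
  cells_per_program: 150
  n_background_genes: 300
  fold_change: 8.0
  baseline_mean: 0.5
  dispersion: 2.0
graph:
  n_pcs: 30
  k: 15
  n_clusters: 16
merge:
  min_cells: 20
  min_degs: 5
  p_adj_max: 0.05
  lfc_min: 0.25
spatial:
  enabled: true
  cells_per_program: 40
  n_other_cells: 60
  field_um: 1000.0
  radius_um: 100.0
  top_k: 20
nuclei:
  enabled: true
  buffer_um: 2.0
stats:
  glm_n_records: 40
  glm_rate_ratio: 1.5
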