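# Demo run: synthetic cohort on a 20-Mb genome, all five stages.
seed: 7

simulate:
  n_chrom: 2
  chrom_length: 10000000
  cpg_spacing: 500
  block_fraction: 0.15
  block_delta: 0.40
  n_ref: 4
  n_case: 4
  tracks:
    tfbs_enriched: {n_features: 3000, feature_length: 400, enrichment: 2.0}
    uniform_sites: {n_features: 3000, feature_length: 400, enrichment: 1.0}
    lad_like: {n_features: 60, feature_length: 100000, enrichment: 2.0, span: true}
  cna:
    altered_fraction: 0.08
    segment_length: 200000
    concentration: 3.0
    n_samples: 10
  expression:
    n_genes: 400
    inblock_var_multiplier: 2.0

blocks:
  tile_size: 5000
  fdr_threshold: 0.05
  min_delta: 0.35
  merge_gap: 250000
  min_block_cpgs: 5

enrichment:
  n_permutations: 200

expression:
  marker: MKI67
  deg_p: 0.01
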