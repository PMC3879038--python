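# Full-pipeline configuration for `triopba run-all`.
# Simulates two populations sharing one causal term with disjoint causal
# genes, then runs QC -> TDT -> gene scoring -> pooled-FDR PBA ->
# size-bias check -> network scan -> cross-population curves.
out_dir: runs/demo
seed: 1
populations: [pop1, pop2]
simulate: true
sim:
  n_trios: 100
  n_snps: 1500
  n_genes: 300
  n_terms: 60
  term_size_range: [8, 20]
  tau: 0.75
  causal_term_ids: [T001]
  causal_genes_per_population:
    pop1: [G0000, G0001, G0002]
    pop2: [G0003, G0004, G0005]
qc: {}          # thresholds: snp_missing_max 0.20, maf_min 0.005, hwe_alpha 1e-5, sample_missing_max 0.05
pba: {}         # levels 3-13, sizes 5-600, alpha_fdr 0.05, rank_percentile transform
network:
  n_start: 10
  n_max: 50
  n_null_samples: 500
crosspop:
  cutoffs: [10, 20, 50, 100, 200, 500]
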