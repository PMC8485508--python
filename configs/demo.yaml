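# Small end-to-end synthetic demonstration (see `gutshift run --config`).
# Three experimental groups, 40 taxa, planted strong pairs (t0,t1), (t2,t3)
# at rho = 0.8, two antibiotic-resistant taxa, Beta-lactam-enriched
# resistome during the treatment window.
outdir: results/demo
seed: 0
stages:
  simulate: true
  preprocess: true
  diversity: true
  trajectories: true
  association: true
  resistome: true
counts_path: null
metadata_path: null
tree_path: null
taxonomy_path: null
table_format: tsv
n_animals_per_group:
  CON: 3
  ABX: 3
  ABXFT: 2
n_taxa: 40
depth_range: [15000, 40000]
perturbation_effect: 4.0
planted_rho: 0.8
n_planted_pairs: 2
n_resistant: 2
fraction_unassigned: 0.05
min_reads: 10000
rarefy_depth: 15000
min_prevalence: 5
other_frac: 0.0001
n_instances: 16
dirichlet_prior: 0.5
shannon_base: 2.0
baseline_day: -4
n_knots: 8
n_perm: 99
lengthscale: 10.0
nugget: 0.1
n_posterior_draws: 25
strong_threshold: 0.5
assoc_groups: [ABX, ABXFT]
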