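# Hypothetical drug, parallel layout: 30% binary covariate on CL,
# 16-point dense schedule vs 2-sample sparse schedule.
name: hypothetical_parallel
model:
  structural: onecomp
  theta: {ka: 0.8, CL: 20.0, V: 70.0, F: 1.0}
  iiv: {ka: 0.1, CL: 0.08, V: 0.1}
  iov: {CL: 0.02}
  covariate_effects:
    - {parameter: CL, covariate: COV, beta: 0.3}
  residual: {kind: proportional, value: 0.1}
  dose_amount: 100.0
design:
  layout: parallel
  dense_arm:
    kind: fixed_times
    times: [0, 0.5, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 16, 20, 24]
  sparse_arm:
    kind: random_subset
    candidate_sets:
      - [0, 0.5, 1, 1.5, 2, 2.5, 3, 4]
      - [5, 6, 8, 10, 12, 16, 20, 24]
pools: {n_with: 500, n_without: 500, seed_dense: 101, seed_sparse: 102}
fit: {inflate: 1.2, seed: 7}
power:
  threshold: 3.84
  n_draws: 10000
  power_target: 80.0
  seed: 2024
  n_max: 200
  paths:
    - dense_only
    - {ratio: [34, 24]}
    - {ratio: [18, 42]}
    - sparse_only
validation:
  replicates: 100
  seed: 11
  designs: [[52, 0], [34, 24], [18, 42], [0, 66]]
  cost: {hosp_dense: 1000, hosp_sparse: 750, assay: 50}
output: mixpower_out/hypothetical_parallel
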