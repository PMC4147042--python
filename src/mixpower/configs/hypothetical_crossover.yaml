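# Hypothetical drug, cross-over layout: covariate present on occasion 1
# only; inter-occasion variability on CL retained in the fitted model.
name: hypothetical_crossover
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
  layout: crossover
  dense_arm:
    kind: fixed_times
    times: [0, 0.5, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 16, 20, 24]
  sparse_arm:
    kind: random_subset
    candidate_sets:
      - [0, 0.5, 1, 1.5, 2, 2.5, 3, 4]
      - [5, 6, 8, 10, 12, 16, 20, 24]
pools: {n_subjects: 500, seed_dense: 201, seed_sparse: 202}
fit: {inflate: 1.2, seed: 7}
power:
  threshold: 3.84
  n_draws: 10000
  power_target: 80.0
  seed: 2024
  n_max: 60
  paths:
    - dense_only
    - {ratio: [5, 4]}
    - {ratio: [3, 7]}
    - sparse_only
validation:
  replicates: 100
  seed: 11
  designs: [[7, 0], [5, 4], [3, 7], [0, 13]]
  cost: {hosp_dense: 1000, hosp_sparse: 750, assay: 50}
output: mixpower_out/hypothetical_crossover
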