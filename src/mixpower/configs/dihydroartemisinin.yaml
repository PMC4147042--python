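# Dihydroartemisinin, parallel layout: 20% pregnancy covariate on CL,
# transit-compartment absorption (n = 7), additive-on-log residual
# (0.58 read as a variance).  Sparse windows differ by pregnancy status.
name: dihydroartemisinin
model:
  structural: transit
  n_transit: 7
  theta: {MTT: 0.982, CL: 78.0, V: 129.0, F: 1.0}
  iiv: {F: 0.0881, V: 0.0162}
  iov: {MTT: 0.23}
  covariate_effects:
    - {parameter: CL, covariate: PREG, beta: 0.2}
  residual: {kind: log_additive, value: 0.58}
  dose_amount: 100.0
design:
  layout: parallel
  dense_arm:
    kind: fixed_times
    times: [0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12]
  sparse_arm:
    by_covariate:
      1:
        kind: windows
        windows: [[0.42, 0.48], [1.2, 3.4], [3.4, 4.9], [6.0, 8.0]]
      0:
        kind: windows
        windows: [[0.28, 0.48], [0.5, 0.95], [2.5, 3.7], [5.8, 6.6]]
pools: {n_with: 500, n_without: 500, seed_dense: 301, seed_sparse: 302}
fit: {inflate: 1.2, seed: 7}
power:
  threshold: 3.84
  n_draws: 10000
  power_target: 80.0
  seed: 2024
  n_max: 300
  paths:
    - dense_only
    - {ratio: [56, 42]}
    - {ratio: [28, 80]}
    - sparse_only
validation:
  replicates: 100
  seed: 11
  designs: [[88, 0], [56, 42], [28, 80], [0, 120]]
  cost: {hosp_dense: 1000, hosp_sparse: 750, assay: 50}
output: mixpower_out/dihydroartemisinin
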