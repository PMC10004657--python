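# Example pipeline configuration for `ioh-ponv run-all --config ...`.
# Every block is optional; omitted keys fall back to the package defaults.

# To analyze real data instead of simulating, provide the two CSV tables
# (see README for the column contracts) and delete the simulate block:
# input:
#   timeseries: data/timeseries.csv
#   cases: data/cases.csv

simulate:
  n_patients: 1000
  seed: 11
  # map_process: {baseline: 79, dip_depth: 20, dip_tau_min: 8,
  #               reversion_per_min: 0.05, noise_sd: 7}
  # true_effect: {spec: time_under_50, beta_nonzero: 0.2, beta_per_unit: 0.05}

features:
  specs: null          # null -> all 24 characterizations

split:
  seed: 12

cv:
  k: 5                 # 10 x 40 reproduces the full-scale protocol
  reps: 5
  seed: 13
  candidates:          # characterizations entering the model comparison
    - time_under_50
    - time_under_60
    - sustained_lowest_1
    - sustained_lowest_5
    - cumulative_lowest_1
    - cumulative_lowest_10
    - fraction_under_60
    - fraction_under_80

model:
  or_x: null           # null -> median and Q3 of the nonzero exposure
  plateau_tol: 0.01    # |d log-odds/dx| below which the curve counts as flat

report:
  plots: true
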