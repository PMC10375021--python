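# Pipeline run configuration for the reference synthetic scenario.
#
# Generate the scenario first (36 months, ~1,000 interviews/month, a
# two-month collection gap — the conditions the estimators are designed
# for), then run the pipeline:
#
#   survtrend simulate --out examples/scenario --seed 0
#   survtrend run --config examples/run.yaml
#
# Paths are resolved relative to this file.

input_dir: scenario/data
output_dir: scenario/out
standard_population: scenario/standard_population.csv
targets:
  1: scenario/targets_level1.csv
  2: scenario/targets_level2.csv
  3: scenario/targets_level3.csv
  4: scenario/targets_level4.csv

# one metric 0-6 score and one binary screen-positive flag
indicators:
  - {name: score, family: gaussian}
  - {name: screen_positive, family: binomial}

strata: [sex, age_group, education]
seed: 0

raking:
  max_iterations: 300
  convergence_tol: 1.0e-6
  min_cell_n: 10
  extreme_factor: 10.0

smoothing:
  enabled: true
  basis_dim: 10
  age_grouping: age3a   # coarse age groups for the factor-by-curve smooths
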