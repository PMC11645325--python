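# Default run configuration.
# The annealer block carries the published experimental settings (minimum
# temperature 2, reheat rate beta 2, tabu length 20, 300 iterations of 8 moves
# each); the search space reproduces the eight tuned learner axes and their
# experimental ranges.
seed: 0
out_dir: edlama_run
input_csv: null
generator:
  n: 10000
  prevalence: 0.0066
  effect_weights:
    esi: 2.5
    waiting_time: -2.5
  correlations:
    - [pulse_rate, respiratory_rate, 0.3]
  seed: 0
degrade_rates: null
impute_k: 5
validate_fraction: 0.1
run_selection: true
selection_tolerance: 0.0001
selection_rf_trees: 100
groups: null
modes: [oversample, undersample]
split_ratio: 0.8
k: 4
threshold: 0.5
atsa:
  t_min: 2.0
  t_init: 100.0
  beta: 2.0
  alpha: 0.95
  tabu_length: 20
  n_iterations: 300
  n_moves: 8
  stall_reheat: 10
  step_scale: 0.1
  seed: 0
space:
  axes:
    - {name: n_estimators, kind: integer, lower: 1, upper: 50}
    - {name: max_depth, kind: integer, lower: 1, upper: 50}
    - {name: max_delta_step, kind: integer, lower: 1, upper: 50}
    - {name: num_parallel_tree, kind: integer, lower: 1, upper: 50}
    - {name: learning_rate, kind: float, lower: 0.0, upper: 1.0, positive: true}
    - {name: reg_alpha, kind: float, lower: 0.0, upper: 1.0, positive: true}
    - {name: reg_lambda, kind: float, lower: 0.0, upper: 1.0, positive: true}
    - {name: gamma, kind: float, lower: 0.0, upper: 50.0, positive: true}
explain_interactions: true
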