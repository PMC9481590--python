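# Small demonstration run: a 10 km x 10 km world with 20,000 people.
seed: 7
thresholds_min: [30, 60, 90, 120, 150, 180]
admin_levels: [0, 1, 2]
world:
  n_rows: 100
  n_cols: 100
  cell_size: 100.0
  n_settlements: 10
  total_population: 20000
  n_rivers: 1
  n_lakes: 1
  admin1_nx: 3
  admin1_ny: 3
schemes:
  - {name: constrained, kind: constrained, census_unit_level: 2, detection_miss_rate: 0.1}
  - {name: unconstrained_uniform, kind: unconstrained_uniform, census_unit_level: 1}
  - {name: unconstrained_covariate, kind: unconstrained_covariate, census_unit_level: 1}
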