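# Small self-contained influenza-vaccination example: one individual sampled
# one day before the dose and on days 1, 3, 7 and 28 after it.
outdir: clonotrack_out
seed: 0
scheme: paired_nt
fold: 2.0
min_cells: 3
t_min: 3
simulated_phase: influenza
simulate:
  seed: 7
  individuals:
    - id: H1
  time_points: [-1, 1, 3, 7, 28]
  cells_per_sample: 400
  clone_size_exponent: 2.5
  persistent_fraction: 0.3
  vaccination:
    dose_days: [0]
    monocyte_fold: 1.5
    n_induced_clonotypes: 20
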