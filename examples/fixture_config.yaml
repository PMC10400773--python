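# Small end-to-end configuration: a quick, fully deterministic run of every
# pipeline stage. Library defaults (Table-sized cohort, 100 SVM repeats) are
# unchanged; this fixture trades cohort size and repeat count for speed.
seed: 0
phantom:
  g: 0.5
  noise_sigma: 10.0
tensor:
  smoothing_fwhm_mm: 6.0
alps:
  use_smoothed: false
cohort:
  n_per_group:
    NC: 20
    MCI: 20
    AD: 20
classify:
  n_repeats: 5
  c_grid: [0.1, 1.0, 10.0]
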