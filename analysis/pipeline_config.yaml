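# Shared configuration of the synthetic flash-FTIR analysis chain.
# Sizes are reduced relative to the full protocol (2,582 wavenumbers,
# 6 us sampling) to keep the drivers fast; the kinetics are unchanged.
seed: 1
kok:
  miss: 0.1
  double_hit: 0.0
  initial_populations: [0.0, 1.0, 0.0, 0.0]
synthetic:
  noise_sigma: 5.0e-7      # OD; heavily averaged step-scan data are sub-uOD
  n_wavenumbers: 64
  n_flashes: 10
  dt_us: 12.0
  pre_flash_ms: 2.0
  post_flash_ms: 130.0
fit:
  fit_start_us: 9.0
  components:
    "S3->S0": [340.0, 2500.0]
    "S1->S2": [33.0, 91.0, 3100.0, 25000.0]
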