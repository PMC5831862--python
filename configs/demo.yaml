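# One-command demo on synthetic data: mirmeta run --config configs/demo.yaml --out runs/demo
simulate:
  seed: 1
  n_families: 30
  n_reads: 2000
  n_mirnas: 40
  loss_rate: 0.1
  ct_noise_sd: 0.1
  stage_effects:
    mir000: {42: 4.0}
    mir001: {42: 0.25}
    mir002: {}
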