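# Small end-to-end demo: phantoms -> morphometry -> one coupled scenario.
out_dir: nucleoflux_out
synth:
  flip_rate: 0.005
  groups:
    - {label: roundish, n: 5, seed: 1}
    - {label: half_spread, n: 5, seed: 2}
    - {label: spread, n: 5, seed: 3}
morph:
  elong_thresh: 0.9
  interval: dispersion
scenarios:
  - {scenario: uniform_spread, t_f: 1.0, t_end: 5.0}
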