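# Typical condition: human category centered at 1.0 (fully human-like).
categories:
  - {mean: 0.5, sd: 0.5, prior: 0.5, label: background}
  - {mean: 1.0, sd: 0.05, prior: 0.5, label: human}
cues:
  - {sigma_s: 0.2, label: S1}
  - {sigma_s: 0.05, label: S2}
alpha: 150.0
beta: 0.5
learning:
  presented_stimulus: 0.4
  delta: 0.1
  n_trials: 500
  variance_floor: 1.0e-6
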