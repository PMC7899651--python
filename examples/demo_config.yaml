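# Demo: two small groups recorded during a retrieval session.
# "modulated" units carry a 3x CS-onset boxcar; "control" units do not.
seed: 7
output_dir: demo_out
protocol:
  kind: RETRIEVAL
classifier:
  z_threshold: 1.96
  min_supra_bins: 2
simulation:
  groups:
    - group_label: modulated
      n_units: 12
      mean_rate_hz: 3.0
      fraction_cs_on: 0.5
      effect_multiplier: 3.0
    - group_label: control
      n_units: 12
      mean_rate_hz: 3.0
  behavior:
    move_to_freeze_cs: 0.30
    freeze_to_move_cs: 0.05
    move_to_freeze_off: 0.02
    freeze_to_move_off: 0.25
    min_bout: 1.0
sampling:
  sample_interval: 5.0
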