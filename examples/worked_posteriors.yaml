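# Worked posterior-probability examples: a local positive likelihood ratio
# observed at a score, and the class prior of the setting it was observed in.
# Feed each through varcal.posterior_from_lr.
- name: enzyme-activity-predictor-high-lr
  lr_plus: 15.0
  prior: 0.25
- name: abundance-predictor-moderate-lr
  lr_plus: 6.0
  prior: 0.21
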