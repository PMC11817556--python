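scenario_id: baseline
description: >
  No interventions active. Parameters frozen by least-squares calibration
  of each outcome stock's adoption/attrition constants to the reported
  baseline trajectory features (peak level, peak window, terminal level).
parameter_file: params_baseline.yaml
sdoh_weights: uniform
interventions: []
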