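scenario_id: outcomes_intervention
description: >
  Access to Healthcare Improvements active at level 0.1 (10%).
  Calibrated so Patient Health Outcomes passes about 1.25 million
  persons in 2025 and declines to about 0.75 million by 2032.
parameter_file: params_outcomes_intervention.yaml
sdoh_weights: uniform
interventions:
  - name: Access to Healthcare Improvements
    targets: [Improved Engagement, Satisfaction Enhancement,
              Enhanced Patient–Provider Communication, Decision-Making and Treatment]
    drag_params: [drag_pe, drag_ps, drag_ce, drag_pho]
    gain: 1.0
    level: 0.1
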