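scenario_id: satisfaction_intervention
description: >
  Access to Healthcare Improvements active at level 0.5 (50%).
  Calibrated so Patient Satisfaction climbs to about 2.4 million persons
  by 2025 and declines to about 0.4 million by 2032. Calibrated
  independently of the baseline scenario (the reported satisfaction
  magnitudes of the two runs are not consistent under one
  parameterization).
parameter_file: params_satisfaction_intervention.yaml
sdoh_weights: uniform
interventions:
  - name: Access to Healthcare Improvements
    targets: [Improved Engagement, Satisfaction Enhancement,
              Enhanced Patient–Provider Communication, Decision-Making and Treatment]
    drag_params: [drag_pe, drag_ps, drag_ce, drag_pho]
    gain: 1.0
    level: 0.5
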