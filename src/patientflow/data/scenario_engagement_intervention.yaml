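scenario_id: engagement_intervention
description: >
  Access to Healthcare Improvements active at level 0.5 (50%), the
  strongest level on the sweep grid; the documented level is an assumption
  recorded in the scenario notes. Calibrated so Patient Engagement peaks
  at about 1.6 million persons between 2022 and 2023.
parameter_file: params_engagement_intervention.yaml
sdoh_weights: uniform
interventions:
  - name: Access to Healthcare Improvements
    targets: [Improved Engagement, Satisfaction Enhancement,
              Enhanced Patient–Provider Communication, Decision-Making and Treatment]
    drag_params: [drag_pe, drag_ps, drag_ce, drag_pho]
    gain: 1.0
    level: 0.5
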