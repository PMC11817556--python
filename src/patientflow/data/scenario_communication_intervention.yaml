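scenario_id: communication_intervention
description: >
  Access to Healthcare Improvements active at level 0.5 (50%).
  Calibrated so Communication Effectiveness peaks at about 6 million
  persons between 2022 and 2026 and declines to about 1 million by 2032
  — roughly 2.5x the baseline communication peak; no stated mechanism
  explains that uplift, so this scenario is calibrated independently.
parameter_file: params_communication_intervention.yaml
sdoh_weights: uniform
interventions:
  - name: Access to Healthcare Improvements
    targets: [Improved Engagement, Satisfaction Enhancement,
              Enhanced Patient–Provider Communication, Decision-Making and Treatment]
    drag_params: [drag_pe, drag_ps, drag_ce, drag_pho]
    gain: 1.0
    level: 0.5
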