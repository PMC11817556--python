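K_ce: 4.0
K_dp: 1.0
K_pe: 3.0
K_pho: 12.0
K_ps: 3.0
alpha_ce: 62.3405862410372
alpha_pe: 17.094087802144358
alpha_pho: 38.84418136667265
alpha_ps: 11.60259222476057
beta_ce: 0.1
beta_pe: 0.1
beta_ps: 0.08
c_ce_pho: 0.15
c_pe_ce: 0.15
c_pe_ps: 0.15
c_ps_pho: 0.15
care_delivery_rate: 0.6
collab_level: 0.7
comorbidity_level: 0.4
comorbidity_load: 0.3
coord_transfer: 0.5
datacoll_level: 0.75
delta0_ce: 4.999999999999998
delta0_pe: 1.7641281718777317
delta0_pho: 1.2049679740702437
delta0_ps: 1.0061398285619512
drag_ce: 0.5
drag_pe: 0.5
drag_pho: 0.5
drag_ps: 0.5
gamma_ce: 1.4682791311550256
gamma_pe: 3.756485550726475
gamma_pho: 1.0053341212360634
gamma_ps: 1.4292972404187618
mha_level: 0.5
pc_level: 0.8
pcc_level: 0.7
quality_transfer: 0.4
sdoh_health_issues: 0.55
sdoh_higher_poverty: 0.5
sdoh_increased_community_violent_crime: 0.35
sdoh_increased_unemployment: 0.4
sdoh_limited_access_to_care: 0.55
sdoh_limited_access_to_quality_food: 0.45
sdoh_limited_english_proficiency: 0.3
sdoh_low_income: 0.5
sdoh_no_health_insurance: 0.45
sdoh_poor_access_to_healthcare: 0.5
sdoh_poor_air_and_water_quality: 0.4
sdoh_poor_communication_with_healthcare_providers: 0.45
sdoh_school_segregation: 0.35
training_level: 0.6
trust_base: 0.6
trust_growth: 0.2
trust_privacy_gain: 0.3
util_rate: 0.08
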