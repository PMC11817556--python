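flow,source,sink,provenance
Improved Engagement,BOUNDARY,Patient Engagement,primary adoption inflow: engagement initiatives draw patients into active involvement
Enhanced Patient Engagement,BOUNDARY,Patient Engagement,secondary inflow: trust built through data privacy draws additional patients in
Insightful Engagement,Patient Engagement,Active Patient Participation,engaged patients graduate into sustained active participation
Satisfaction Enhancement,BOUNDARY,Patient Satisfaction,primary adoption inflow: trusted engaged care raises the satisfied population
Satisfaction Feedback,BOUNDARY,Patient Satisfaction,secondary inflow: awareness programs feed satisfaction through feedback channels
Satisfaction Assurance,Patient Satisfaction,BOUNDARY,attrition: assured cases exit the actively satisfied pool over time
Enhanced Patient–Provider Communication,BOUNDARY,Communication Effectiveness,primary adoption inflow: collaboration among professionals builds effective communication
Optimized Patient–Provider Interaction,BOUNDARY,Communication Effectiveness,secondary inflow: training programs optimize patient-provider interaction
Insights for Enhanced Care,Communication Effectiveness,BOUNDARY,attrition: communication gains erode as insights are absorbed into routine care
Decision-Making and Treatment,BOUNDARY,Patient Health Outcomes,primary adoption inflow: informed decisions and treatment improve the outcomes population
Enhancement Feedback Outcome,Patient Health Outcomes,BOUNDARY,attrition: outcome gains decay as comorbidity and systemic constraints accumulate
Trust Development,BOUNDARY,Data Privacy,privacy compliance and trust accumulate toward a practical ceiling
Coordinated Care Delivery,BOUNDARY,Care Coordination,patient-centric culture drives coordinated delivery of care
Coordination Impact on Quality,Care Coordination,Quality of Care,coordination is converted into quality of care
Resource Utilization,Resources Allocation,Quality of Care,allocated resources are consumed to sustain quality of care
Treatment Quality Impacts,Quality of Care,Patient Health Status,quality of care accrues into overall patient health status
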