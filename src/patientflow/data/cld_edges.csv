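source,target,polarity,provenance
Patient Engagement,Patient Satisfaction,POSITIVE,care chain: engagement improves satisfaction
Patient Satisfaction,Active Patient Participation,POSITIVE,care chain: satisfied patients participate actively
Active Patient Participation,Patient Education Programs,POSITIVE,care chain: participation feeds practical education programs
Patient Education Programs,Outcome-Informed Practices,POSITIVE,care chain: education enables outcome-informed practices
Outcome-Informed Practices,Patient Empowerment,POSITIVE,care chain: informed practices empower patients
Patient Empowerment,Patient-Centric Care,POSITIVE,care chain: empowerment initiatives strengthen patient-centric care
Patient-Centric Care,Patient Engagement,POSITIVE,care chain: patient-centric care drives engagement
Perceived Usefulness,Intention to Participate,POSITIVE,intention chain: perceived usefulness raises intention to take part
Perceived Ease of Use,Intention to Participate,POSITIVE,intention chain: ease of use raises intention to take part
Intention to Participate,Patient Engagement,POSITIVE,intention chain: intention converts into engagement
Patient Engagement,Clinical Outcomes,POSITIVE,intention chain: involvement in decisions improves clinical outcomes
Clinical Outcomes,Perceived Usefulness,POSITIVE,intention chain: good outcomes confirm perceived usefulness
Service Creation,Iterative Correction,POSITIVE,tech loop: new services undergo iterative correction
Iterative Correction,Smooth Tech Integration,POSITIVE,tech loop: correction smooths technology integration
Smooth Tech Integration,Continuous Improvements,POSITIVE,tech loop: integration sustains continuous improvement
Continuous Improvements,Service Creation,POSITIVE,tech loop: improvements spawn new service creation
Smooth Tech Integration,Health Condition Tracking,POSITIVE,tech loop: integration enables telecare-based tracking
Health Condition Tracking,Patient Empowerment,POSITIVE,tech loop: tracking supports self-empowerment
Patient Empowerment,Continuous Improvements,POSITIVE,tech loop: empowered patients push continuous improvement
Continuous Improvements,Smooth Tech Integration,POSITIVE,tech loop: improvement cycles reinforce integration
Patient Experience,Digital Health Innovation,POSITIVE,digital loop: patient experience shapes digital innovation
Digital Health Innovation,Digital Health Tools,POSITIVE,digital loop: innovation yields digital health tools
Digital Health Tools,Patient Empowerment,POSITIVE,digital loop: online tools and apps empower patients
Patient Empowerment,Patient Experience,POSITIVE,digital loop: empowerment improves patient experience
Resources Allocation,Streamlined Delivery,POSITIVE,resource loop: allocation streamlines delivery processes
Streamlined Delivery,Quality of Care,POSITIVE,resource loop: streamlined processes raise quality of care
Quality of Care,Long-Term Sustainability,POSITIVE,resource loop: quality supports long-term sustainability
Long-Term Sustainability,Provider Incentives,POSITIVE,resource loop: sustainable systems fund provider incentives
Provider Incentives,Resources Allocation,POSITIVE,resource loop: incentivized providers replenish allocation
Quality of Care,Patient Satisfaction,POSITIVE,cross link: quality of care raises patient satisfaction
Resources Allocation,Service Requests,POSITIVE,authorization loop: available resources expand service requests
Service Requests,Authorization Review,POSITIVE,authorization loop: requests trigger utilization review
Authorization Review,Resources Allocation,NEGATIVE,authorization loop: review denials constrain further allocation
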