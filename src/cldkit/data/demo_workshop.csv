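group_id,cause,effect,polarity,delay,cause_is_action,effect_is_action
demo,trauma,substance_abuse,+,0,0,0
demo,substance_abuse,domestic_violence,+,0,0,0
demo,domestic_violence,trauma,+,0,0,0
demo,trauma,mental_health_stigma,-,0,0,0
demo,mental_health_stigma,dementia,+,0,0,0
demo,substance_abuse,healthy_lifestyle,-,0,0,0
demo,healthy_lifestyle,chronic_disease_risk,-,0,0,0
demo,chronic_disease_risk,medication_side_effects,+,0,0,0
demo,medication_side_effects,dementia,+,0,0,0
demo,chronic_disease_risk,dementia,+,0,0,0
demo,health_literacy,knowledge_of_dementia_signs,+,0,0,0
demo,knowledge_of_dementia_signs,early_family_intervention,+,0,0,0
demo,early_family_intervention,family_caregiving,+,0,0,0
demo,family_caregiving,dementia_information_dissemination,+,0,0,0
demo,dementia_information_dissemination,health_literacy,+,0,0,0
demo,social_isolation,family_structure,-,0,0,0
demo,family_structure,positive_youth_behaviors,+,0,0,0
demo,positive_youth_behaviors,youth_hope,+,0,0,0
demo,youth_hope,crime,-,0,0,0
demo,crime,criminal_justice_bias,+,0,0,0
demo,criminal_justice_bias,convictions,+,0,0,0
demo,convictions,access_to_quality_jobs,-,0,0,0
demo,access_to_quality_jobs,crime,-,0,0,0
demo,dementia,family_caregiving,+,0,0,0
demo,family_caregiving,access_to_quality_jobs,-,0,0,0
demo,access_to_quality_jobs,income,+,0,0,0
demo,income,caregiving_quality,+,0,0,0
demo,caregiving_quality,dementia,-,1,0,0
demo,youth_hope,education,+,0,0,0
demo,education,ignorance,-,0,0,0
demo,ignorance,health_literacy,-,0,0,0
demo,dementia,out_of_pocket_expenses,+,0,0,0
demo,out_of_pocket_expenses,poverty,+,0,0,0
demo,dementia,insurance_cost,+,0,0,0
demo,insurance_cost,income,-,0,0,0
demo,poverty,income,-,0,0,0
demo,discriminatory_policies,school_funding,-,0,0,0
demo,school_funding,school_quality,+,0,0,0
demo,school_quality,education,+,0,0,0
demo,education,poverty,-,1,0,0
demo,poverty,political_apathy,+,0,0,0
demo,political_apathy,policy_influence_capacity,-,0,0,0
demo,policy_influence_capacity,discriminatory_policies,-,0,0,0
demo,family_caregiving,health_literacy,+,0,0,0
demo,early_family_intervention,caregiving_quality,+,0,0,0
demo,health_literacy,mental_health_stigma,-,0,0,0
demo,mental_health_stigma,distress_and_anxiety,+,0,0,0
demo,distress_and_anxiety,dementia,+,0,0,0
demo,dementia_information_campaign,health_literacy,+,0,1,0
demo,voter_mobilization,policy_influence_capacity,+,0,1,0
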