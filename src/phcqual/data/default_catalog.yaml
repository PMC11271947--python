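# Default indicator catalogue: 3 domains, 13 sub-domains.
# This catalogue is a synthetic stand-in for an unavailable survey-instrument
# appendix: indicator ids follow the definitional clauses of each sub-domain,
# not the wording of any real questionnaire.
indicators:
  # --- PHC system / accessibility (patient survey) ---
  - {id: acc_travel_time_ok, sub_domain: accessibility, source: patient survey, rule: {kind: identity}}
  - {id: acc_affordable_visit, sub_domain: accessibility, source: patient survey, rule: {kind: identity}}
  - {id: acc_provider_available, sub_domain: accessibility, source: patient survey, rule: {kind: identity}}
  - {id: acc_services_in_time, sub_domain: accessibility, source: patient survey, rule: {kind: identity}}
  # --- PHC system / comprehensiveness ---
  - {id: com_health_education, sub_domain: comprehensiveness, source: patient survey, rule: {kind: identity}}
  - {id: com_preventive_care, sub_domain: comprehensiveness, source: patient survey, rule: {kind: identity}}
  - {id: com_common_disease_care, sub_domain: comprehensiveness, source: patient survey, rule: {kind: identity}}
  - {id: com_referral_available, sub_domain: comprehensiveness, source: patient survey, rule: {kind: identity}}
  - {id: com_health_management, sub_domain: comprehensiveness, source: patient survey, rule: {kind: identity}}
  # --- PHC system / continuity ---
  - {id: con_management_followup, sub_domain: continuity, source: patient survey, rule: {kind: identity}}
  - {id: con_informational_records, sub_domain: continuity, source: patient survey, rule: {kind: identity}}
  - {id: con_relational_same_provider, sub_domain: continuity, source: patient survey, rule: {kind: identity}}
  - {id: con_consistent_advice, sub_domain: continuity, source: patient survey, rule: {kind: identity}}
  # --- PHC system / coordination ---
  - {id: coo_family_doctor_contract, sub_domain: coordination, source: patient survey, rule: {kind: identity}}
  - {id: coo_health_record_established, sub_domain: coordination, source: patient survey, rule: {kind: identity}}
  - {id: coo_referral_coordinated, sub_domain: coordination, source: patient survey, rule: {kind: identity}}
  - {id: coo_information_shared_across, sub_domain: coordination, source: patient survey, rule: {kind: identity}}
  # --- clinical care / assessment (chart abstraction, Rasch-scored) ---
  - {id: ast_history_taken, sub_domain: assessment, source: chart abstraction, rule: {kind: identity}}
  - {id: ast_symptom_inquiry, sub_domain: assessment, source: chart abstraction, rule: {kind: identity}}
  - {id: ast_risk_classified, sub_domain: assessment, source: chart abstraction, rule: {kind: identity}}
  - {id: ast_baseline_measured, sub_domain: assessment, source: chart abstraction, rule: {kind: identity}}
  - {id: ast_lifestyle_assessed, sub_domain: assessment, source: chart abstraction, rule: {kind: identity}}
  # --- clinical care / diagnosis ---
  - {id: dia_lab_tests_adequate, sub_domain: diagnosis, source: chart abstraction, rule: {kind: identity}}
  - {id: dia_examination_performed, sub_domain: diagnosis, source: chart abstraction, rule: {kind: identity}}
  - {id: dia_evidence_documented, sub_domain: diagnosis, source: chart abstraction, rule: {kind: identity}}
  - {id: dia_differential_considered, sub_domain: diagnosis, source: chart abstraction, rule: {kind: identity}}
  # --- clinical care / treatment ---
  - {id: trt_medication_appropriate, sub_domain: treatment, source: chart abstraction, rule: {kind: identity}}
  - {id: trt_no_overuse, sub_domain: treatment, source: chart abstraction, rule: {kind: identity}}
  - {id: trt_no_underuse, sub_domain: treatment, source: chart abstraction, rule: {kind: identity}}
  - {id: trt_referral_timely, sub_domain: treatment, source: chart abstraction, rule: {kind: identity}}
  - {id: trt_hospitalization_advised, sub_domain: treatment, source: chart abstraction, rule: {kind: identity}}
  # --- clinical care / disease management (patient survey + registry) ---
  - {id: dmg_personalized_plan, sub_domain: disease management, source: patient survey, rule: {kind: identity}}
  - {id: dmg_risk_assessed, sub_domain: disease management, source: patient survey, rule: {kind: identity}}
  - {id: dmg_effectiveness_reviewed, sub_domain: disease management, source: patient survey, rule: {kind: identity}}
  - {id: dmg_followup_frequency_adequate, sub_domain: disease management, source: registry,
     rule: {kind: threshold, field: followups_per_year, op: ">=", value: 4}}
  # --- clinical care / provider competence (vignettes, Rasch-scored) ---
  - {id: vig_01, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_02, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_03, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_04, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_05, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_06, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_07, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  - {id: vig_08, sub_domain: provider competence, source: provider survey, rule: {kind: identity}}
  # --- user experience / shared decision-making ---
  - {id: sdm_opinion_included, sub_domain: shared decision-making, source: patient survey, rule: {kind: identity}}
  - {id: sdm_options_discussed, sub_domain: shared decision-making, source: patient survey, rule: {kind: identity}}
  - {id: sdm_joint_treatment_plan, sub_domain: shared decision-making, source: patient survey, rule: {kind: identity}}
  - {id: sdm_preferences_asked, sub_domain: shared decision-making, source: patient survey, rule: {kind: identity}}
  # --- user experience / family-centeredness ---
  - {id: fam_family_history_inquired, sub_domain: family-centeredness, source: patient survey, rule: {kind: identity}}
  - {id: fam_family_health_asked, sub_domain: family-centeredness, source: patient survey, rule: {kind: identity}}
  - {id: fam_family_in_care_plan, sub_domain: family-centeredness, source: patient survey, rule: {kind: identity}}
  - {id: fam_family_lifestyle_support, sub_domain: family-centeredness, source: patient survey, rule: {kind: identity}}
  # --- user experience / information sharing ---
  - {id: inf_records_accessible, sub_domain: information sharing, source: patient survey, rule: {kind: identity}}
  - {id: inf_results_explained, sub_domain: information sharing, source: patient survey, rule: {kind: identity}}
  - {id: inf_unbiased_information, sub_domain: information sharing, source: patient survey, rule: {kind: identity}}
  - {id: inf_files_available, sub_domain: information sharing, source: patient survey, rule: {kind: identity}}
  # --- user experience / respect for patient preferences ---
  - {id: rsp_privacy_respected, sub_domain: respect for patient preferences, source: patient survey, rule: {kind: identity}}
  - {id: rsp_time_for_questions, sub_domain: respect for patient preferences, source: patient survey, rule: {kind: identity}}
  - {id: rsp_choices_valued, sub_domain: respect for patient preferences, source: patient survey, rule: {kind: identity}}
  - {id: rsp_concerns_listened, sub_domain: respect for patient preferences, source: patient survey, rule: {kind: identity}}
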