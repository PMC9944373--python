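{
  "name": "seclusion-falls-skeleton",
  "top": "TOP_FALL",
  "metadata": {
    "provenance": "reconstruction",
    "illustrative": true,
    "note": "Critical-path architecture of a patient fall in a psychiatric seclusion room: a fall requires a disorder, a mechanism of fall, a reason for falling, and failure of both fall-risk assessment and fall-prevention intervention. Structure reconstructed from published prose; this is not the full 88-factor elicited model."
  },
  "gates": [
    {"id": "TOP_FALL", "kind": "AND", "inputs": ["DISORDER", "MECHANISM", "REASON", "PREVENTION_FAILURE"]},
    {"id": "DISORDER", "kind": "OR", "inputs": ["schizophrenia", "bipolar_disorder", "psychiatric_comorbidity", "alzheimers", "lewy_body_dementia", "personality_disorder"]},
    {"id": "MECHANISM", "kind": "OR", "inputs": ["getting_out_of_bed", "seated_to_standing", "getting_to_bed", "slipping", "tripping", "stumbling"]},
    {"id": "REASON", "kind": "OR", "inputs": ["REASON_PSYCHOLOGICAL", "REASON_PHYSICAL"]},
    {"id": "REASON_PSYCHOLOGICAL", "kind": "OR", "inputs": ["agitation", "impaired_attention"]},
    {"id": "REASON_PHYSICAL", "kind": "OR", "inputs": ["narrow_base_of_support", "obesity", "gait_abnormality", "MEDICATION_SIDE_EFFECT"]},
    {"id": "MEDICATION_SIDE_EFFECT", "kind": "OR", "inputs": ["dizziness", "muscle_weakness", "arrhythmia"]},
    {"id": "PREVENTION_FAILURE", "kind": "AND", "inputs": ["RISK_ASSESSMENT_FAILURE", "INTERVENTION_FAILURE"]},
    {"id": "RISK_ASSESSMENT_FAILURE", "kind": "OR", "inputs": ["risk_assessment_not_performed", "risk_assessment_inaccurate"]},
    {"id": "INTERVENTION_FAILURE", "kind": "OR", "inputs": ["no_preventive_intervention", "intervention_ineffective"]}
  ],
  "events": [
    {"id": "schizophrenia", "label": "Schizophrenia", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "bipolar_disorder", "label": "Bipolar disorder", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "psychiatric_comorbidity", "label": "Psychiatric comorbidity", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "alzheimers", "label": "Alzheimer's disease", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "lewy_body_dementia", "label": "Lewy body dementia", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "personality_disorder", "label": "Personality disorder", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "getting_out_of_bed", "label": "Getting out of bed", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "seated_to_standing", "label": "From seated to standing position", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "getting_to_bed", "label": "Getting to bed", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "slipping", "label": "Slipping", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "tripping", "label": "Tripping", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "stumbling", "label": "Stumbling", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "agitation", "label": "Agitation", "theme": "patient_behavior", "underdeveloped": false, "sources": []},
    {"id": "impaired_attention", "label": "Impaired attention", "theme": "patient_behavior", "underdeveloped": true, "sources": []},
    {"id": "narrow_base_of_support", "label": "Narrow base of support", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "obesity", "label": "Obesity", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "gait_abnormality", "label": "Gait abnormality", "theme": "physical_condition", "underdeveloped": false, "sources": []},
    {"id": "dizziness", "label": "Dizziness (medication side effect)", "theme": "medication", "underdeveloped": false, "sources": []},
    {"id": "muscle_weakness", "label": "Muscle weakness (medication side effect)", "theme": "medication", "underdeveloped": false, "sources": []},
    {"id": "arrhythmia", "label": "Arrhythmia (medication side effect)", "theme": "medication", "underdeveloped": true, "sources": []},
    {"id": "risk_assessment_not_performed", "label": "Fall-risk assessment not performed", "theme": "prevention", "underdeveloped": false, "sources": []},
    {"id": "risk_assessment_inaccurate", "label": "Fall-risk assessment inaccurate", "theme": "prevention", "underdeveloped": true, "sources": []},
    {"id": "no_preventive_intervention", "label": "No fall-prevention intervention", "theme": "prevention", "underdeveloped": false, "sources": []},
    {"id": "intervention_ineffective", "label": "Fall-prevention intervention ineffective", "theme": "prevention", "underdeveloped": true, "sources": []}
  ]
}
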