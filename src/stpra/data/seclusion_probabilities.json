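{
  "note": "Illustrative probability overlay for the seclusion-falls skeleton. These values are synthetic: chosen at published-plausible magnitudes for psychiatric inpatient fall risk so the analysis pipeline can be demonstrated end to end. They are NOT the elicited probabilities of the original 88-factor model.",
  "illustrative": true,
  "sources": {
    "schizophrenia": [
      {"value": 0.32, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.38, "provenance": "literature", "citation_label": "synthetic-lit-b"},
      {"value": 0.29, "provenance": "literature", "citation_label": "synthetic-lit-c"}
    ],
    "bipolar_disorder": [
      {"value": 0.22, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.27, "provenance": "literature", "citation_label": "synthetic-lit-b"}
    ],
    "psychiatric_comorbidity": [
      {"value": 0.18, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.24, "provenance": "literature", "citation_label": "synthetic-lit-b"}
    ],
    "alzheimers": [
      {"value": 0.09, "provenance": "literature", "citation_label": "synthetic-lit-a"}
    ],
    "lewy_body_dementia": [
      {"value": 0.06, "provenance": "literature", "citation_label": "synthetic-lit-a"}
    ],
    "personality_disorder": [
      {"value": 0.11, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.07, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ],
    "getting_out_of_bed": [
      {"value": 0.30, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.41, "provenance": "literature", "citation_label": "synthetic-lit-b"},
      {"value": 0.25, "provenance": "literature", "citation_label": "synthetic-lit-c"}
    ],
    "seated_to_standing": [
      {"value": 0.28, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.36, "provenance": "literature", "citation_label": "synthetic-lit-b"}
    ],
    "getting_to_bed": [
      {"value": 0.17, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.21, "provenance": "literature", "citation_label": "synthetic-lit-b"}
    ],
    "slipping": [
      {"value": 0.12, "provenance": "literature", "citation_label": "synthetic-lit-a"}
    ],
    "tripping": [
      {"value": 0.08, "provenance": "literature", "citation_label": "synthetic-lit-a"}
    ],
    "stumbling": [
      {"value": 0.10, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ],
    "agitation": [
      {"value": 0.25, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.19, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ],
    "impaired_attention": [
      {"value": 0.14, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ],
    "narrow_base_of_support": [
      {"value": 0.16, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.22, "provenance": "literature", "citation_label": "synthetic-lit-b"}
    ],
    "obesity": [
      {"value": 0.24, "provenance": "literature", "citation_label": "synthetic-lit-a"}
    ],
    "gait_abnormality": [
      {"value": 0.19, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.27, "provenance": "literature", "citation_label": "synthetic-lit-b"},
      {"value": 0.15, "provenance": "literature", "citation_label": "synthetic-lit-c"}
    ],
    "dizziness": [
      {"value": 0.21, "provenance": "literature", "citation_label": "synthetic-lit-a"},
      {"value": 0.16, "provenance": "literature", "citation_label": "synthetic-lit-b"}
    ],
    "muscle_weakness": [
      {"value": 0.18, "provenance": "literature", "citation_label": "synthetic-lit-a"}
    ],
    "arrhythmia": [
      {"value": 0.05, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ],
    "risk_assessment_not_performed": [
      {"value": 0.15, "provenance": "expert", "citation_label": "synthetic-exp-a"},
      {"value": 0.22, "provenance": "expert", "citation_label": "synthetic-exp-b"}
    ],
    "risk_assessment_inaccurate": [
      {"value": 0.12, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ],
    "no_preventive_intervention": [
      {"value": 0.10, "provenance": "expert", "citation_label": "synthetic-exp-a"},
      {"value": 0.18, "provenance": "expert", "citation_label": "synthetic-exp-b"}
    ],
    "intervention_ineffective": [
      {"value": 0.13, "provenance": "expert", "citation_label": "synthetic-exp-a"}
    ]
  }
}
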