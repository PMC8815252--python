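{
  "age_templates": [
    "{age} year old",
    "{age} year old patient"
  ],
  "medical_history": [
    "history of hypertension",
    "hypertension, diabetes mellitus",
    "history of atrial fibrillation",
    "coronary artery disease on aspirin",
    "chronic kidney disease stage 2",
    "history of asthma",
    "hyperlipidemia on statin",
    "history of depression and anxiety",
    "gastroesophageal reflux disease",
    "obesity and obstructive sleep apnea"
  ],
  "social_history": [
    "{py} pack-year smoker",
    "former smoker quit {n} years ago",
    "social alcohol use",
    "denies tobacco or alcohol use",
    "lives alone, independent in daily activities"
  ]
}
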