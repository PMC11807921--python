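{
  "model": "EuroSCORE II",
  "intercept": -5.324537,
  "age": {
    "coefficient": 0.0285181,
    "threshold": 60,
    "rule": "x = 1 if age <= threshold else age - threshold + 1"
  },
  "binary": {
    "female": 0.2196434,
    "extracardiac_arteriopathy": 0.5360268,
    "poor_mobility": 0.2407181,
    "previous_cardiac_surgery": 1.118599,
    "chronic_lung_disease": 0.1886564,
    "active_endocarditis": 0.6194522,
    "critical_preoperative_state": 1.086517,
    "insulin_dependent_diabetes": 0.3542749,
    "ccs4": 0.2226147,
    "recent_mi": 0.1528943,
    "thoracic_aorta": 0.6527205
  },
  "categorical": {
    "renal": {
      "normal": 0.0,
      "moderate": 0.303553,
      "severe": 0.8592256,
      "dialysis": 0.6421508
    },
    "nyha": {
      "I": 0.0,
      "II": 0.1070545,
      "III": 0.2958358,
      "IV": 0.5597929
    },
    "lv_function": {
      "good": 0.0,
      "moderate": 0.3150652,
      "poor": 0.8084096,
      "very_poor": 0.9346919
    },
    "pulmonary_hypertension": {
      "none": 0.0,
      "moderate": 0.1788899,
      "severe": 0.3491475
    },
    "urgency": {
      "elective": 0.0,
      "urgent": 0.3174673,
      "emergency": 0.7039121,
      "salvage": 1.362947
    },
    "weight_of_intervention": {
      "isolated_cabg": 0.0,
      "single_non_cabg": 0.0062118,
      "two_procedures": 0.5521478,
      "three_procedures": 0.9724533
    }
  }
}
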