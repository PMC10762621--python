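{
  "description": "Published summary counts from the source study, used as inputs to arithmetic consistency checks.",
  "severity_table": {
    "tg_only": {"edge": 4788, "mild_moderate": 13994, "severe": 7821},
    "tg_plus_chol": {"edge": 2225, "mild_moderate": 4989, "severe": 2477},
    "pregnant_tg_only": {"edge": 27, "mild_moderate": 134, "severe": 83},
    "pregnant_tg_plus_chol": {"edge": 25, "mild_moderate": 94, "severe": 43}
  },
  "checks": [
    {"id": "t1", "name": "male share of gender-recognized records", "op": "percent",
     "numerator": 7495, "denominator": 13155, "decimals": 2, "expected": 56.97},
    {"id": "t2", "name": "pregnant share of female patients", "op": "percent",
     "numerator": 895, "denominator": 5660, "decimals": 1, "expected": 15.8},
    {"id": "t3", "name": "symptom-reporting share of all consultations", "op": "percent",
     "numerator": 8888, "denominator": 69845, "decimals": 1, "expected": 12.7},
    {"id": "t4", "name": "TG-only share of TG-detected records", "op": "percent",
     "numerator": 26603, "denominator": 36294, "decimals": 1, "expected": 73.3},
    {"id": "t5", "name": "TG-detected records total (cohort additivity)", "op": "sum",
     "terms": [26603, 9691], "expected": 36294},
    {"id": "t6", "name": "edge-elevation total across cohorts", "op": "sum",
     "terms": [4788, 2225], "expected": 7013},
    {"id": "t7", "name": "severe-elevation total across cohorts", "op": "sum",
     "terms": [7821, 2477], "expected": 10298},
    {"id": "t8", "name": "responses per query, online consultation platforms", "op": "rate",
     "responses": 61677, "total_queries": 69845, "platform_share": 0.47,
     "decimals": 2, "expected": 1.88},
    {"id": "t9", "name": "two-drug share of combination users", "op": "percent",
     "numerator": 236, "denominator": 275, "decimals": 1, "expected": 85.8},
    {"id": "t10", "name": "severe share of pregnant TG-only patients", "op": "percent",
     "numerator": 83, "denominator": 244, "decimals": 0, "expected": 34},
    {"id": "t11", "name": "mild-moderate share of pregnant TG+cholesterol patients", "op": "percent",
     "numerator": 94, "denominator": 162, "decimals": 1, "expected": 58.0},
    {"id": "t12", "name": "dietary-control share of lifestyle-intervention mentions", "op": "percent",
     "numerator": 657, "denominator": 1259, "decimals": 1, "expected": 52.2}
  ]
}
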