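{
  "language": "en",
  "categories": {
    "I-a": ["hypertriglyceridemia", "high tg", "mixed hyperlipidemia"],
    "I-b": ["hyperlipidemia", "dyslipidemia", "thick blood lipids", "three high"],
    "II-a": ["triglyceride", "triacylglycerol", "tg"],
    "II-b": ["blood lipid"],
    "III": ["diet", "food"],
    "IV-a": ["bate", "fenofibrate", "lipanthyl", "bezafibrate"],
    "IV-b": [
      "statin", "lipid-lowering drug",
      "lovastatin", "simvastatin", "pravastatin", "fluvastatin",
      "atorvastatin", "rosuvastatin", "pitavastatin",
      "niacin", "ezetimibe", "probucol", "fish oil",
      "xuezhikang", "zhibituo", "zhikening"
    ]
  }
}
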