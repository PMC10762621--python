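{
  "language": "zh",
  "categories": {
    "I-a": ["高甘油三酯血症", "甘油三酯高", "混合性高脂血症"],
    "I-b": ["高脂血症", "高血脂", "血脂异常", "血脂稠", "三高"],
    "II-a": ["甘油三酯", "三酸甘油脂", "甘油三脂", "tg"],
    "II-b": ["血脂"],
    "III": ["饮食", "食物"],
    "IV-a": ["贝特", "非诺贝特", "力平之", "苯扎贝特"],
    "IV-b": [
      "他汀", "降脂药",
      "洛伐他汀", "辛伐他汀", "普伐他汀", "氟伐他汀",
      "阿托伐他汀", "瑞舒伐他汀", "匹伐他汀",
      "烟酸", "依折麦布", "普罗布考", "鱼油",
      "血脂康", "脂必妥", "脂可宁"
    ]
  }
}
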