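{
  "language": "zh",
  "link_tokens": ["http://", "https://", "www.", "点击链接", "扫码", "加群"],
  "promotion_markers": ["我们的产品", "本诊所", "特效", "优惠", "折扣", "立即订购", "免费试用"],
  "science_markers": ["是一种", "本文", "百科", "是指", "科普", "小知识:"]
}
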