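{
  "clauses": [
    {"kind": "single", "categories": ["I-a"]},
    {"kind": "single", "categories": ["II-a"]},
    {"kind": "single", "categories": ["IV-a"]},
    {"kind": "pair", "categories": ["I-a", "II-a"]},
    {"kind": "pair", "categories": ["I-a", "II-b"]},
    {"kind": "pair", "categories": ["I-a", "III"]},
    {"kind": "pair", "categories": ["I-a", "IV-a"]},
    {"kind": "pair", "categories": ["I-a", "IV-b"]},
    {"kind": "pair", "categories": ["II-a", "I-b"]},
    {"kind": "pair", "categories": ["II-a", "III"]},
    {"kind": "pair", "categories": ["II-a", "IV-a"]},
    {"kind": "pair", "categories": ["II-a", "IV-b"]},
    {"kind": "pair", "categories": ["IV-a", "I-b"]},
    {"kind": "pair", "categories": ["IV-a", "II-b"]}
  ]
}
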