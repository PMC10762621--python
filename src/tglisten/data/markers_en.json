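{
  "language": "en",
  "link_tokens": ["http://", "https://", "www.", "click the link", "scan the code", "add the group"],
  "promotion_markers": ["our product", "our clinic", "miracle", "special offer", "discount", "order now", "free trial"],
  "science_markers": [
    "are a kind of", "is a kind of", "are a type of", "is a type of",
    "this article", "encyclopedia", "refers to", "in this popular science",
    "let us explain", "health knowledge:"
  ]
}
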