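{
  "name": "aq",
  "kind": "aq_binary",
  "n_items": 50,
  "response_min": 1,
  "response_max": 4,
  "agree_items": [2, 4, 5, 6, 7, 9, 12, 13, 16, 18, 19, 20, 21, 22, 23, 26, 33, 35, 39, 41, 42, 43, 45, 46],
  "agree_responses": [1, 2],
  "note": "Binary scoring: one point when the response side (agree = options 1-2, disagree = 3-4, collapsing slightly/definitely) matches the item's key. Key is editable config."
}
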