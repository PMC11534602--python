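{
  "name": "gmsi_pa",
  "kind": "likert",
  "n_items": 9,
  "response_min": 1,
  "response_max": 7,
  "reverse_items": [],
  "subscales": {}
}
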