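{
  "name": "ios",
  "kind": "ios",
  "n_items": 1,
  "response_min": 1,
  "response_max": 7,
  "note": "Seven-step circle-overlap pictorial scale, mapped linearly to 0-100%."
}
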