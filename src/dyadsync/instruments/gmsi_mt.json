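{
  "name": "gmsi_mt",
  "kind": "likert",
  "n_items": 7,
  "response_min": 1,
  "response_max": 7,
  "reverse_items": [],
  "subscales": {},
  "note": "Musical-training subscale; year-band items are mapped to 1-7 before scoring (see map_years_to_band)."
}
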