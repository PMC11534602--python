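{
  "name": "pitch_test",
  "kind": "pitch",
  "n_items": 10,
  "response_min": 0,
  "response_max": 1,
  "answer_key": [1, 0, 1, 1, 0, 1, 0, 1, 1, 0],
  "note": "10 chord pairings from the 4 chord classes: C(4,2)=6 'different' pairs (response 1) and 4 'same' pairs (response 0)."
}
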