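{
  "name": "ebmrq",
  "kind": "likert",
  "n_items": 24,
  "response_min": 1,
  "response_max": 5,
  "reverse_items": [],
  "subscales": {
    "music_seeking": [1, 2, 3, 4],
    "emotion_evocation": [5, 6, 7, 8],
    "mood_regulation": [9, 10, 11, 12],
    "sensorimotor": [13, 14, 15, 16],
    "social": [17, 18, 19, 20],
    "musical_absorption": [21, 22, 23, 24]
  },
  "note": "Synthetic default item-to-subscale assignment and reversal key; edit to match a specific administration."
}
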