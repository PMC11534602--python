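# dyadsync

Analysis pipeline for **dyadic synchronization–continuation tapping
experiments**: does the pleasantness of a jointly produced sound shape how
tightly two people synchronize their movements?

In the paradigm this package analyzes, two participants tap along with a
metronome (synchronization phase) and then keep the tempo together after it
stops (continuation phase). Each tap sounds a pure-tone note, so
simultaneous taps form a two-note chord that is nominally *consonant*
(Perf5, Maj6) or *dissonant* (Min2, Maj2); after every trial both
participants rate the pleasure of the sound they created (1–10). The design
crosses metronome IOI (450/550/650 ms) × feedback-tone duration
(150/200/400 ms) × 8 chord note-assignments = 72 trials per dyad.

The package provides, end to end:

- **Event model & TSV I/O** (`dyadsync.events`) — trial conditions, click
  schedules, taps, gong, ratings; a validated long-format event-log format
  plus a questionnaire table.
- **Generative simulator** (`dyadsync.simulate`) — a linear
  phase-correction loop around two-level (timekeeper + motor)
  Wing–Kristofferson noise with symmetric partner coupling
  `t_i(n+1) = t_i(n) + IOI − α·A_i(n) − β′·(t_i(n) − t_j(n)) + ε`,
  where consonance multiplies the coupling gain β and shifts the mean
  pleasure rating. Known ground truth makes every downstream estimate
  checkable by parameter/effect recovery.
- **Preprocessing** (`dyadsync.preprocess`) — nearest-neighbour tap
  pairing Δt = |tap_A − tap_B|, tap-to-click matching (signed Δt = tap −
  click), glitch/post-gong/0.8·IOI exclusions, inter-tap intervals, and
  per-trial measures including the log-transformed mean absolute difference.
- **Inference** (`dyadsync.stats`) — fully-within repeated-measures ANOVA
  with generalized eta squared (ηG², Olejnik–Algina), Holm post-hocs,
  per-dyad pleasure–synchrony slopes with a group t-test, dyad consonance
  effects (consonant − dissonant mean log ms), Pearson correlations.
- **Questionnaires** (`dyadsync.questionnaires`) — IOS closeness (percent),
  eBMRQ (6 subscales), Gold-MSI musical training / perceptual abilities,
  AQ, and the 10-pair chord-discrimination test, with editable JSON keys.
- **Pipeline & CLI** (`dyadsync.pipeline`, console script `dyadsync`) —
  `dyadsync all --config run.yaml --seed 17 --out results/` runs
  simulate → preprocess → analyze → report deterministically and writes a
  manifest with every seed and parameter.

## Worked example

The numbered scripts under `analysis/` run the complete study on simulated
data (21 dyads × 72 trials, effect world: consonance multiplies coupling by
1.5 and is rated ~0.4 points higher):

```
$ python analysis/01_simulate.py
simulated 1512 trials for 21 dyads (seed 17)
injected recording glitches in 7 trials

$ python analysis/02_preprocess.py
glitch trials: 7 (0.463% of trials)
pairs excluded: 0 post-gong (0.0%), 126 over threshold (0.212%)
mean absolute tap difference (sync phase): 33.9 ms

$ python analysis/03_inferential_stats.py
interpersonal consonance effect: F(1,20) = 112.18, p = 0.0000, etaG2 = 0.069
log mean abs difference: consonant 3.552 vs dissonant 3.614 log ms
pleasure-synchrony slopes (synchrony = -log abs diff): mean 0.042, t(20) = 13.14, p = 2.68e-11
dyad consonance effects: mean -0.0692 log ms, 20/21 dyads negative
```

Reading the output: dyads synchronized more tightly (lower log mean
absolute tap difference) on consonant trials, the effect shows up in 20 of
21 simulated dyads, and trials rated more pleasant were tapped more tightly
together (positive slope of the synchrony score on the dyad's mean rating).
`analysis/04_questionnaires_correlations.py` adds instrument scores and
dyad-level correlations; `analysis/05_calibration.py` verifies on 100
replicate experiments per world that the consonance test rejects at the
nominal 5% rate when no effect exists and recovers the effect when it does.

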