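# Methods

## Task and event model

A trial consists of a programmatic metronome (clicks exactly on the IOI
grid), two participants' tap onsets, an end-of-trial gong, and two pleasure
ratings. All times are milliseconds from trial start, stored as floats.
Defaults follow the task description: 4 lead-in clicks (participants join
at the fifth), 20 tapped synchronization clicks, and a continuation phase
of 20 further beats, with the gong at `last_click + 20·IOI`. Both counts
are configurable on `TrialCondition` because "20 clicks" is ambiguous
between 20 total and 20 tapped; we take 20 tapped after 4 lead-ins.

A tap belongs to the continuation phase if it falls later than half an IOI
after the final click. No rule is forced by the task itself; the half-IOI
boundary is symmetric and keeps a final synchronization tap that lags its
click inside the synchronization phase. Events after the gong are never
phase-labelled — they carry an exclusion flag instead.

The chord table fixes the note assignment for each of the 8 chord ids;
consonance is a pure function of the chord (Min2/Maj2 dissonant,
Perf5/Maj6 consonant). Event logs are long-format UTF-8 TSV, one event per
row, sorted by (dyad, trial, time); reading is strict — unknown event
types, non-monotone tap times, or out-of-range ratings raise with the
offending row number rather than truncating.

## Timing model

Each agent is a linear phase-correction loop with two-level noise:

    t_i(n+1) = t_i(n) + IOI − α_i·A_i(n) − β_i′·(t_i(n) − t_j(n))
               + e_tk(n) + e_m(n+1) − e_m(n)

- `A_i(n)` — signed asynchrony to the scheduled click (synchronization
  phase only; the continuation update drops the α term and replaces the IOI
  by the agent's internal interval, compounded by `tempo_drift` per beat).
- `e_tk ~ N(0, σ_tk²)` — central timekeeper noise; `e_m ~ N(0, σ_m²)` —
  motor noise entering as a first difference (the two-level model of
  self-paced tapping).
- `β′ = β · beta_gain_consonant` on consonant trials — the single
  mechanism by which chord quality affects behaviour in the simulator:
  consonance tightens mutual coupling.

For an uncoupled agent the asynchrony follows
`A(n+1) = (1−α)A(n) + e_tk(n) + Δe_m`, whose stationary variance has the
closed form `(σ_tk² + 2ασ_m²)/(α(2−α))`. This is the simulator's main
oracle: the tests require Monte-Carlo agreement within 3 standard errors
over 2,500 replicates, and at α = 1 with zero noise an initial offset is
corrected in exactly one step.

Coupling uses the difference of the agents' most recent tap times — the
simplest signal both agents share through auditory feedback. First taps are
initialized at the fifth click ± N(0, σ_tk). A configuration whose
asynchrony exceeds 5·IOI raises a simulation error naming the trial.

**Stability note.** Raising β tightens synchrony only while the combined
difference-mode gain α + 2β′ stays at or below ~1; beyond that the
difference mode over-corrects and oscillates. The monotonicity property is
therefore asserted with the null effect configuration (so nominal β is
effective β) at α = 0.5, β ≤ 0.4.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α (metronome correction) | 0.5 | – | mid-range of empirically reported phase-correction gains; keeps α + 2β′ ≤ 1 for all consonance conditions |
| β (partner coupling) | 0.15 | – | modest mutual coupling; difference mode stable in both phases |
| σ_tk | 25 | ms | with σ_m below, puts the mean absolute tap difference at ~35–40 ms, matching the observed scale of dyadic tapping (~50 ms means, log-means ~3.6–3.8) |
| σ_m | 12 | ms | roughly half the timekeeper SD, the usual two-level-model regime |
| beta_gain_consonant | 1.5 | – | effect-world coupling modulation |
| rating means | 6.4 / 6.0 | rating points | consonant vs dissonant, matching the observed ~0.4-point gap on a 1–10 scale |
| rating σ | 1.5 | rating points | observed between-trial rating spread |
| rating_sync_weight | 0 (2.0 in the effect world) | rating per log-ms | wires ratings to the trial's realized synchrony so pleasure–synchrony slopes are recoverable |
| per-dyad jitter | 0.1 | lognormal σ | between-dyad heterogeneity for realistic group-level variance |

Ratings are drawn per participant from a normal around the
consonance-dependent mean, optionally shifted by
`rating_sync_weight · (log mean |Δt| − log 50)`, rounded and clipped to
[1, 10]; the pipeline averages the two members per trial. Randomness flows
master seed → per-dyad stream → per-trial stream (numpy `SeedSequence`), so
identical seeds give byte-identical logs.

## Preprocessing

Matching is directional: every A tap at or before the gong is paired with
the B tap minimizing |Δt| (B taps reusable; ties to the earlier tap). A
mutual-nearest one-to-one variant is available behind a flag for
sensitivity analysis. Exclusions, in order of precedence: trials where a
participant produced no taps are dropped from interpersonal analyses
(retained for the recorded participant's individual measures); pairs whose
B member falls after the gong; pairs with |Δt| > 0.8·IOI (strict — exactly
0.8·IOI is kept). Each excluded pair carries exactly one reason, and
per-phase used + excluded counts always sum to the number of pre-gong A
taps.

Per-trial measures: mean absolute difference and its natural log per phase
(natural log chosen because log-mean magnitudes of ~3.7 correspond to
~40–50 ms means); signed tap−click mean and SD per participant
(synchronization phase only); ITI mean and SD per participant
(continuation only); the whole-trial pooled log mean used by the per-trial
pleasure regression and the dyad consonance effect; and the dyad-mean
rating. A phase with no usable pairs yields missing values, never zeros.
Moment diagnostics use population moments (skewness g1, non-excess
kurtosis m4/m2², so a normal sample sits near 3).

## Inference

The repeated-measures ANOVA applies the Moebius (inclusion–exclusion)
sum-of-squares decomposition to the complete units × cells array; each
effect is tested against its interaction with the unit factor, with exact
dfs and no sphericity correction by default (matching the conventional
univariate analysis; Greenhouse–Geisser is available behind a flag).
Generalized eta squared for fully-within designs is
`SS_effect / (SS_effect + Σ SS(unit-related terms))`, which in a one-factor
design reduces to `SS_A/(SS_A + SS_subjects + SS_error)`. Degenerate
inputs: an exactly null effect reports F = 0; an exactly null error term
with a non-null effect reports F = ∞; incomplete grids and single units are
hard errors, because the design is complete by construction.

Aggregation to cell means is an unweighted mean of per-trial values; an
empty design cell is an error listing the offending (unit, cell), never a
silent drop. Holm adjustment delegates to statsmodels' step-down
implementation (validated against hand-worked examples); note the Holm map
is *not* idempotent in general, so only dominance over the raw p-values and
sorted-order monotonicity are asserted.

The pleasure–synchrony slope is an ordinary least-squares fit per dyad of
the synchrony score on the dyad's mean rating, followed by a one-sample t
of the slopes against zero. The synchrony score defaults to the *negated*
log mean absolute difference so that a positive slope reads "more pleasure,
tighter synchrony"; the raw-log alternative is exposed via
`convention="log"` because the original sign convention is ambiguous.
Dyads with fewer than 3 usable trials or zero rating variance are skipped
with a warning and excluded from the group test. The dyad consonance
effect is the mean consonant minus mean dissonant whole-trial log mean;
negative values mean consonance tightened synchrony. Correlations are
Pearson with two-sided t-based p (no rank method is implied by the
analyses reproduced); all tests are two-sided at α = 0.05.

## Questionnaires

Likert instruments are summed with per-item reversal where keyed; the AQ
scores one point per item whose response side (agree = options 1–2,
disagree = 3–4, collapsing "slightly"/"definitely") matches the item's
agree/disagree key; Gold-MSI musical training maps year bands
(0, 1, 2, 3, 4–5, 6–9, 10+) to 1–7 before summing; the IOS circle-overlap
step maps linearly to percent, `(level−1)/(n_levels−1)·100`, on a 7-step
scale (the pictorial variant's exact step count is not standardized, so
`n_levels` is a parameter). Item keys ship as editable JSON files under
`dyadsync/instruments/` — the shipped eBMRQ subscale assignment and
reversal key are synthetic defaults to be edited for a specific
administration; the score ceilings (120, 49, 63, 50, 100%) are enforced
regardless. The pitch test scores 10 same/different judgements against a
key with 6 "different" (the C(4,2) unordered chord pairs) and 4 "same"
items, and the group is tested against the chance level of 5.

## What the generator does and does not emulate

Emulated: the full factorial design and trial counts, mutual adaptation
with consonance-dependent coupling, two-level timing noise at a realistic
magnitude, consonance-dependent and synchrony-dependent pleasure ratings,
between-dyad parameter heterogeneity, occasional recording glitches, and
pre/post closeness change in the questionnaire generator. Not emulated:
tempo-dependent noise scaling (noise SDs are constant across IOIs),
leader–follower asymmetry, serial dependence of ratings, missing single
taps within a trial, item-level psychometric structure beyond the scoring
keys, and any true covariance between questionnaire traits and tapping
parameters — so passing tests certify the pipeline's arithmetic and its
statistical calibration, not claims about real dyads.

## Problem sizes and numerical choices

Calibration and recovery studies use scaled-down experiments — 10 dyads ×
24 trials (3 IOIs × 1 feedback duration × 8 chords), analyzed with a
consonance × IOI × phase ANOVA — chosen so that 400 null and 200
effect-world replicates complete in a couple of minutes while keeping the
per-replicate design fully crossed. Under the null world the consonance
test rejects at 5% ± Monte-Carlo error; under the effect world the mean
dyad consonance effect is negative in ~100% of replicates, significant and
correctly signed in a majority, and group pleasure slopes are positive.
The demo experiment in the acceptance script is full-scale (21 dyads × 72
trials) and round-trips the event log through TSV before analysis.

Tie-breaks in both nearest-neighbour matchers go to the earlier event;
matching is invariant to shifting all times by a constant. The ANOVA's
degenerate-effect tolerance is 1e-12 of the grid's overall mean square.
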