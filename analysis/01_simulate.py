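#!/usr/bin/env python
"""Simulate the full dyadic tapping experiment and write the raw logs.

21 dyads x 72 trials (3 IOIs x 3 feedback durations x 8 chords), with the
consonance-tightens-coupling effect world and pleasure ratings wired to the
trial's realized synchrony, plus per-participant questionnaire responses.
Outputs: results/data/events.tsv, questionnaires.tsv, ground_truth.json.
"""

import dataclasses
import json
from pathlib import Path

from dyadsync.events import write_event_log, write_questionnaire_log
from dyadsync.experiments import EFFECT_WORLD
from dyadsync.simulate import simulate_experiment, simulate_questionnaires

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials, truth = simulate_experiment(
        21, effects=EFFECT_WORLD, master_seed=SEED, glitch_rate=0.005
    )
    write_event_log(trials, OUT / "events.tsv")
    dyads = sorted({t.condition.dyad_id for t in trials})
    write_questionnaire_log(
        simulate_questionnaires(dyads, master_seed=SEED), OUT / "questionnaires.tsv"
    )
    (OUT / "ground_truth.json").write_text(
        json.dumps(
            {
                "master_seed": truth["master_seed"],
                "effects": dataclasses.asdict(truth["effects"]),
                "param_template": dataclasses.asdict(truth["param_template"]),
            },
            indent=2,
        )
    )
    n_glitch = sum(1 for t in trials if not t.taps_a or not t.taps_b)
    print(f"simulated {len(trials)} trials for {len(dyads)} dyads (seed {SEED})")
    print(f"injected recording glitches in {n_glitch} trials")
    print(f"logs written under {OUT}")


if __name__ == "__main__":
    main()
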