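#!/usr/bin/env python
"""Questionnaire scoring and dyad-level correlation analyses.

Scores every instrument, checks pitch discrimination against chance,
tests the pre-to-post closeness change, and correlates the dyad-summed
predictor scores with the consonance effect and with overall interpersonal
synchronization.
"""

from pathlib import Path

import pandas as pd

from dyadsync.events import read_event_log, read_questionnaire_log
from dyadsync.pipeline import analyze

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_event_log(ROOT / "data" / "events.tsv")
    measures = pd.read_csv(ROOT / "trial_measures.tsv", sep="\t")
    qframe = read_questionnaire_log(ROOT / "data" / "questionnaires.tsv")
    results = analyze(trials, measures, qframe)

    for key in ("participant_scores", "dyad_sums", "correlations"):
        results[key].to_csv(ROOT / f"{key}.tsv", sep="\t", index=False)

    pitch = results["pitch_test"]
    print(
        f"pitch test: {pitch['mean_correct']:.2f}/10 correct "
        f"(t({pitch['df']}) = {pitch['t_vs_chance']:.2f} vs chance = 5)"
    )
    ios = results["ios_change"]
    print(
        f"closeness change (post - pre IOS): {ios['mean_change_pct']:.1f}% "
        f"(t({ios['df']}) = {ios['t']:.2f}, p = {ios['p']:.4f})"
    )
    print("correlations with dyad-level outcomes:")
    for _, row in results["correlations"].iterrows():
        print(
            f"  {row['outcome']} ~ {row['predictor']}: "
            f"r = {row['r']:+.2f} (p = {row['p']:.3f}, n = {row['n']})"
        )


if __name__ == "__main__":
    main()
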