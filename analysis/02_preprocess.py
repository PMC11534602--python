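#!/usr/bin/env python
"""Tap matching, exclusions and per-trial measures from the simulated log.

Reads results/data/events.tsv, pairs each A tap with the nearest B tap,
applies the exclusion rules (glitch trials, post-gong taps, pairs with
|difference| > 80% of the IOI), and writes the tidy per-(dyad, trial, phase)
measures table plus an exclusion report.
"""

import json
from pathlib import Path

from dyadsync.events import read_event_log
from dyadsync.pipeline import exclusion_report
from dyadsync.preprocess import trial_measures_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_event_log(ROOT / "data" / "events.tsv")
    measures = trial_measures_frame(trials)
    measures.to_csv(ROOT / "trial_measures.tsv", sep="\t", index=False)
    report = exclusion_report(trials, measures)
    (ROOT / "exclusions.json").write_text(json.dumps(report, indent=2))
    print(f"parsed {report['n_trials']} trials")
    print(
        f"glitch trials: {report['glitch_trials']} "
        f"({report['glitch_trials_pct']}% of trials)"
    )
    print(
        f"pairs excluded: {report['pairs_excluded_post_gong']} post-gong "
        f"({report['pairs_excluded_post_gong_pct']}%), "
        f"{report['pairs_excluded_over_threshold']} over threshold "
        f"({report['pairs_excluded_over_threshold_pct']}%)"
    )
    sync = measures[measures["phase"] == "synchronization"]
    print(
        "mean absolute tap difference (sync phase): "
        f"{sync['mean_abs_diff_ms'].mean():.1f} ms"
    )


if __name__ == "__main__":
    main()
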