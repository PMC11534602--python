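"""Tap matching, exclusion rules and per-trial timing measures.

Interpersonal synchronization is quantified by pairing each tap of
participant A with the nearest-in-time tap of participant B and taking the
per-trial mean of the absolute differences |tap A - tap B| (log-transformed
downstream). Individual precision uses the signed difference between each
synchronization-phase tap and its nearest metronome click, and the inter-tap
intervals (ITIs) of the continuation phase.

Exclusion rules applied, in order: trials where a participant produced no
taps are dropped from interpersonal analyses (recording glitches); taps after
the end-of-trial gong are excluded; matched pairs whose absolute difference
exceeds 80% of the metronome IOI are excluded (the dyad had not started
synchronizing yet). The 80% threshold is strict: a difference of exactly
0.8*IOI is kept.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import Phase, TrialEvents, assign_phase

__all__ = [
    "MatchedPair",
    "MetronomeMatch",
    "TrialMeasures",
    "detect_glitch_trial",
    "nearest_index",
    "pair_dyad_taps",
    "match_taps_to_metronome",
    "compute_itis",
    "summarize_trial",
    "moment_diagnostics",
    "trial_measures_frame",
]

POST_GONG = "post_gong"
OVER_THRESHOLD = "over_threshold"


@dataclass(frozen=True)
class MatchedPair:
    """An A tap and its nearest B tap, with exclusion bookkeeping."""

    tap_a_ms: float
    tap_b_ms: float
    abs_diff_ms: float
    phase: Phase
    excluded: bool = False
    reason: Optional[str] = None  # POST_GONG | OVER_THRESHOLD


@dataclass(frozen=True)
class MetronomeMatch:
    """A tap matched to its nearest metronome click (signed, tap - click)."""

    tap_ms: float
    click_ms: float
    signed_diff_ms: float


def detect_glitch_trial(trial: TrialEvents) -> bool:
    """True when either participant has no recorded taps.

    Such trials are dropped from interpersonal analyses but kept for the
    individual analyses of whichever participant was recorded.
    """
    return not trial.taps_a or not trial.taps_b


def nearest_index(sorted_ref: Sequence[float], t: float) -> int:
    """Index of the element of ``sorted_ref`` nearest to ``t``; ties go to
    the earlier element."""
    i = bisect_left(sorted_ref, t)
    if i == 0:
        return 0
    if i == len(sorted_ref):
        return len(sorted_ref) - 1
    before, after = sorted_ref[i - 1], sorted_ref[i]
    # tie (equidistant) resolves to the earlier event
    if t - before <= after - t:
        return i - 1
    return i


def pair_dyad_taps(
    taps_a: Sequence[float],
    taps_b: Sequence[float],
    ioi_ms: float,
    clicks: Sequence[float],
    gong_ms: float,
) -> list[MatchedPair]:
    """Directional nearest-neighbour pairing of A taps to B taps.

    Every A tap at or before the gong is paired with the B tap minimizing the
    absolute difference (B taps may be reused; ties break to the earlier B
    tap). Pairs are then flagged ``post_gong`` when the B member falls after
    the gong, or ``over_threshold`` when the absolute difference exceeds
    0.8 * IOI; each excluded pair carries exactly one reason, post-gong
    taking precedence. The pair's phase is that of the A tap.
    """
    if not taps_a or not taps_b:
        return []
    pairs: list[MatchedPair] = []
    for ta in taps_a:
        if ta > gong_ms:
            continue
        tb = taps_b[nearest_index(taps_b, ta)]
        diff = abs(ta - tb)
        phase = assign_phase(ta, clicks, ioi_ms, gong_ms)
        assert phase is not None  # ta <= gong by construction
        if tb > gong_ms:
            pairs.append(MatchedPair(ta, tb, diff, phase, True, POST_GONG))
        elif diff > 0.8 * ioi_ms:
            pairs.append(MatchedPair(ta, tb, diff, phase, True, OVER_THRESHOLD))
        else:
            pairs.append(MatchedPair(ta, tb, diff, phase))
    return pairs


def pair_dyad_taps_mutual(
    taps_a: Sequence[float],
    taps_b: Sequence[float],
    ioi_ms: float,
    clicks: Sequence[float],
    gong_ms: float,
) -> list[MatchedPair]:
    """One-to-one mutual-nearest variant of :func:`pair_dyad_taps`.

    Keeps only pairs where the A tap and B tap are each other's nearest
    neighbours; provided for sensitivity analysis, not the primary pipeline.
    """
    directional = pair_dyad_taps(taps_a, taps_b, ioi_ms, clicks, gong_ms)
    kept: list[MatchedPair] = []
    for pair in directional:
        back = taps_a[nearest_index(taps_a, pair.tap_b_ms)]
        if back == pair.tap_a_ms:
            kept.append(pair)
    return kept


def match_taps_to_metronome(
    taps: Sequence[float],
    clicks: Sequence[float],
    ioi_ms: Optional[float] = None,
    gong_ms: float = math.inf,
) -> list[MetronomeMatch]:
    """Match synchronization-phase taps to their nearest metronome click.

    Signed difference is tap - click (negative = anticipation). Ties between
    two equidistant clicks resolve to the earlier click. Taps outside the
    synchronization phase (or after the gong) are ignored; an empty result is
    returned when no sync-phase taps exist.
    """
    if not clicks:
        raise ValueError("clicks must be non-empty")
    if ioi_ms is None:
        if len(clicks) < 2:
            raise ValueError("cannot infer IOI from a single click")
        ioi_ms = clicks[1] - clicks[0]
    matches: list[MetronomeMatch] = []
    for tap in taps:
        phase = assign_phase(tap, clicks, ioi_ms, gong_ms)
        if phase is not Phase.SYNCHRONIZATION:
            continue
        click = clicks[nearest_index(clicks, tap)]
        matches.append(MetronomeMatch(tap, click, tap - click))
    return matches


def compute_itis(
    taps: Sequence[float],
    clicks: Sequence[float],
    ioi_ms: float,
    gong_ms: float = math.inf,
) -> list[float]:
    """First differences of a participant's continuation-phase taps (ms)."""
    cont = [
        t
        for t in taps
        if assign_phase(t, clicks, ioi_ms, gong_ms) is Phase.CONTINUATION
    ]
    return [t1 - t0 for t0, t1 in zip(cont, cont[1:])]


def moment_diagnostics(values: Sequence[float]) -> tuple[float, float]:
    """Skewness g1 = m3/m2^1.5 and non-excess kurtosis m4/m2^2.

    Population (biased) moments; a normal distribution gives kurtosis ~= 3.
    Raises ``ValueError`` for fewer than three or constant values, where the
    moments are undefined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values for moment diagnostics")
    if np.ptp(arr) == 0:
        raise ValueError("moments undefined for constant input")
    skew = float(sps.skew(arr, bias=True))
    kurt = float(sps.kurtosis(arr, fisher=False, bias=True))
    return skew, kurt


@dataclass
class TrialMeasures:
    """Derived per-trial quantities, per phase and per participant.

    Phase-level fields are dicts keyed by :class:`Phase`; a phase with no
    usable pairs is simply absent from the dict (missing-with-reason, never
    zero). ``log_mean_abs_diff`` is the natural log of the phase's mean
    absolute tap difference in ms.
    """

    dyad_id: str
    trial_index: int
    mean_abs_diff_ms: dict[Phase, float]
    log_mean_abs_diff: dict[Phase, float]
    n_pairs_used: dict[Phase, int]
    n_pairs_excluded: dict[Phase, int]
    n_excluded_post_gong: dict[Phase, int]
    n_excluded_over_threshold: dict[Phase, int]
    mean_signed_ms: dict[str, float]  # per participant, sync phase
    sd_signed_ms: dict[str, float]
    mean_iti_ms: dict[str, float]  # per participant, continuation phase
    sd_iti_ms: dict[str, float]
    mean_rating: Optional[float]
    # whole-trial interpersonal measure (both phases pooled), used by the
    # per-trial pleasure regression and the dyad consonance effect
    trial_mean_abs_diff_ms: Optional[float] = None
    trial_log_mean_abs_diff: Optional[float] = None


def summarize_trial(trial: TrialEvents, mutual: bool = False) -> TrialMeasures:
    """Compute every per-trial measure from raw events.

    Interpersonal means use non-excluded pairs only. Signed tap-metronome
    statistics are restricted to the synchronization phase; ITIs to the
    continuation phase.
    """
    cond = trial.condition
    pair_fn = pair_dyad_taps_mutual if mutual else pair_dyad_taps
    pairs = pair_fn(trial.taps_a, trial.taps_b, cond.ioi_ms, trial.clicks, trial.gong_ms)

    mean_abs: dict[Phase, float] = {}
    log_mean: dict[Phase, float] = {}
    n_used: dict[Phase, int] = {Phase.SYNCHRONIZATION: 0, Phase.CONTINUATION: 0}
    n_excl: dict[Phase, int] = {Phase.SYNCHRONIZATION: 0, Phase.CONTINUATION: 0}
    n_gong: dict[Phase, int] = {Phase.SYNCHRONIZATION: 0, Phase.CONTINUATION: 0}
    n_thresh: dict[Phase, int] = {Phase.SYNCHRONIZATION: 0, Phase.CONTINUATION: 0}
    for phase in Phase:
        usable = [p.abs_diff_ms for p in pairs if p.phase is phase and not p.excluded]
        n_used[phase] = len(usable)
        n_excl[phase] = sum(1 for p in pairs if p.phase is phase and p.excluded)
        n_gong[phase] = sum(
            1 for p in pairs if p.phase is phase and p.reason == POST_GONG
        )
        n_thresh[phase] = sum(
            1 for p in pairs if p.phase is phase and p.reason == OVER_THRESHOLD
        )
        if usable:
            m = float(np.mean(usable))
            mean_abs[phase] = m
            if m > 0:
                log_mean[phase] = math.log(m)

    all_usable = [p.abs_diff_ms for p in pairs if not p.excluded]
    trial_mean = float(np.mean(all_usable)) if all_usable else None
    trial_log = math.log(trial_mean) if trial_mean else None

    mean_signed: dict[str, float] = {}
    sd_signed: dict[str, float] = {}
    mean_iti: dict[str, float] = {}
    sd_iti: dict[str, float] = {}
    for who, taps in (("A", trial.taps_a), ("B", trial.taps_b)):
        if not taps:
            continue
        signed = [
            m.signed_diff_ms
            for m in match_taps_to_metronome(
                taps, trial.clicks, cond.ioi_ms, trial.gong_ms
            )
        ]
        if signed:
            mean_signed[who] = float(np.mean(signed))
            sd_signed[who] = float(np.std(signed, ddof=1)) if len(signed) > 1 else 0.0
        itis = compute_itis(taps, trial.clicks, cond.ioi_ms, trial.gong_ms)
        if itis:
            mean_iti[who] = float(np.mean(itis))
            sd_iti[who] = float(np.std(itis, ddof=1)) if len(itis) > 1 else 0.0

    return TrialMeasures(
        dyad_id=cond.dyad_id,
        trial_index=cond.trial_index,
        mean_abs_diff_ms=mean_abs,
        log_mean_abs_diff=log_mean,
        n_pairs_used=n_used,
        n_pairs_excluded=n_excl,
        n_excluded_post_gong=n_gong,
        n_excluded_over_threshold=n_thresh,
        mean_signed_ms=mean_signed,
        sd_signed_ms=sd_signed,
        mean_iti_ms=mean_iti,
        sd_iti_ms=sd_iti,
        mean_rating=trial.mean_rating,
        trial_mean_abs_diff_ms=trial_mean,
        trial_log_mean_abs_diff=trial_log,
    )


def trial_measures_frame(
    trials: Iterable[TrialEvents], mutual: bool = False
) -> pd.DataFrame:
    """Tidy per-trial measures table: one row per (dyad, trial, phase).

    Glitch trials (a participant with zero taps) contribute no interpersonal
    rows but keep the recorded participant's individual columns. Condition
    columns are carried along; this table is the input contract for the
    stats layer.
    """
    rows = []
    for trial in trials:
        cond = trial.condition
        glitch = detect_glitch_trial(trial)
        measures = summarize_trial(trial, mutual=mutual)
        for phase in Phase:
            row = {
                "dyad_id": cond.dyad_id,
                "trial_index": cond.trial_index,
                "ioi_ms": cond.ioi_ms,
                "feedback_ms": cond.feedback_ms,
                "chord_id": cond.chord_id,
                "consonance": cond.consonance,
                "phase": phase.value,
                "glitch": glitch,
                "mean_rating": measures.mean_rating,
                "trial_mean_abs_diff_ms": None if glitch else measures.trial_mean_abs_diff_ms,
                "trial_log_mean_abs_diff": None if glitch else measures.trial_log_mean_abs_diff,
                "mean_abs_diff_ms": None if glitch else measures.mean_abs_diff_ms.get(phase),
                "log_mean_abs_diff": None if glitch else measures.log_mean_abs_diff.get(phase),
                "n_pairs_used": 0 if glitch else measures.n_pairs_used[phase],
                "n_pairs_excluded": 0 if glitch else measures.n_pairs_excluded[phase],
                "n_excluded_post_gong": 0 if glitch else measures.n_excluded_post_gong[phase],
                "n_excluded_over_threshold": 0 if glitch else measures.n_excluded_over_threshold[phase],
            }
            if phase is Phase.SYNCHRONIZATION:
                for who in ("A", "B"):
                    row[f"mean_signed_ms_{who.lower()}"] = measures.mean_signed_ms.get(who)
                    row[f"sd_signed_ms_{who.lower()}"] = measures.sd_signed_ms.get(who)
            else:
                for who in ("A", "B"):
                    row[f"mean_iti_ms_{who.lower()}"] = measures.mean_iti_ms.get(who)
                    row[f"sd_iti_ms_{who.lower()}"] = measures.sd_iti_ms.get(who)
            rows.append(row)
    return pd.DataFrame(rows)
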