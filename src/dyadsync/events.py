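"""Data model and tabular I/O for synchronization-continuation tapping trials.

The experiment modelled here is a (dyadic) synchronization-continuation task:
a metronome clicks at a fixed inter-onset interval (IOI); participants start
tapping at the fifth click, synchronize for a block of clicks, and then keep
tapping at the same tempo after the metronome stops (continuation phase) until
an end-of-trial gong. In the dyadic variant each tap of each participant
sounds a pure-tone note so that simultaneous taps form a two-note chord that
is nominally consonant (Perf5, Maj6) or dissonant (Min2, Maj2).

All times are milliseconds from trial start, stored as floats; the metronome
is programmatic so clicks fall exactly on the IOI grid. Event logs are
exchanged as long-format UTF-8 TSV files, one event per row (see
:func:`write_event_log` for the schema).
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PITCH_HZ",
    "ChordAssignment",
    "CHORD_TABLE",
    "SOLO_CHORD_TABLE",
    "IOI_SET",
    "FEEDBACK_SET",
    "Phase",
    "DesignCell",
    "TrialCondition",
    "TrialEvents",
    "EventLogError",
    "build_condition_grid",
    "assign_phase",
    "event_log_frame",
    "write_event_log",
    "read_event_log",
    "write_questionnaire_log",
    "read_questionnaire_log",
]

#: Feedback-tone frequencies (Hz) available to the participants.
PITCH_HZ: dict[str, float] = {
    "C": 261.0,
    "C#": 277.18,
    "E": 329.63,
    "F": 349.23,
    "G": 392.0,
    "A": 440.0,
    "B": 493.88,
    "D": 587.33,
}

CONSONANT = "consonant"
DISSONANT = "dissonant"

#: Metronome inter-onset intervals used in the design (ms).
IOI_SET: tuple[int, ...] = (450, 550, 650)
#: Auditory feedback (tone) durations used in the design (ms).
FEEDBACK_SET: tuple[int, ...] = (150, 200, 400)


@dataclass(frozen=True)
class ChordAssignment:
    """One row of the chord table: which note each dyad member plays.

    ``chord_id`` 0 is reserved for the solo (individual-task) feedback tone,
    which has no chord and no consonance class.
    """

    chord_id: int
    note_a: str
    note_b: str
    chord: Optional[str]  # interval name, e.g. "Min2"
    consonance: Optional[str]  # "consonant" | "dissonant" | None (solo)

    def __post_init__(self) -> None:
        if self.note_a not in PITCH_HZ or self.note_b not in PITCH_HZ:
            raise ValueError(f"unknown pitch in chord {self.chord_id}")
        if self.consonance not in (CONSONANT, DISSONANT, None):
            raise ValueError(f"bad consonance label {self.consonance!r}")

    @property
    def freq_a(self) -> float:
        return PITCH_HZ[self.note_a]

    @property
    def freq_b(self) -> float:
        return PITCH_HZ[self.note_b]


#: The eight note assignments of the dyadic task. Min2/Maj2 chords are the
#: dissonant half of the design, Perf5/Maj6 the consonant half.
CHORD_TABLE: tuple[ChordAssignment, ...] = (
    ChordAssignment(1, "C", "C#", "Min2", DISSONANT),
    ChordAssignment(2, "C#", "C", "Min2", DISSONANT),
    ChordAssignment(3, "G", "A", "Maj2", DISSONANT),
    ChordAssignment(4, "A", "G", "Maj2", DISSONANT),
    ChordAssignment(5, "E", "B", "Perf5", CONSONANT),
    ChordAssignment(6, "B", "E", "Perf5", CONSONANT),
    ChordAssignment(7, "D", "F", "Maj6", CONSONANT),
    ChordAssignment(8, "F", "D", "Maj6", CONSONANT),
)

#: Single A-440 feedback tone of the individual task (no chord).
SOLO_CHORD_TABLE: tuple[ChordAssignment, ...] = (
    ChordAssignment(0, "A", "A", None, None),
)

_CHORD_BY_ID = {c.chord_id: c for c in CHORD_TABLE + SOLO_CHORD_TABLE}


class Phase(str, enum.Enum):
    """Task phase: paced by the metronome, or self-paced continuation."""

    SYNCHRONIZATION = "synchronization"
    CONTINUATION = "continuation"


@dataclass(frozen=True)
class DesignCell:
    """One cell of the condition grid (IOI x feedback duration x chord)."""

    ioi_ms: float
    feedback_ms: float
    chord: ChordAssignment


def build_condition_grid(
    ioi_set: Sequence[float] = IOI_SET,
    feedback_set: Sequence[float] = FEEDBACK_SET,
    chord_table: Sequence[ChordAssignment] = CHORD_TABLE,
) -> list[DesignCell]:
    """Full cross product of the design factors, in deterministic order.

    Returns one :class:`DesignCell` per (ioi, feedback, chord) combination,
    ascending in that factor order. The canonical dyadic design
    (3 IOIs x 3 durations x 8 chords) yields 72 cells; the individual task
    (solo tone) yields 9.
    """
    if not ioi_set or not feedback_set or not chord_table:
        raise ValueError("design factor sets must be non-empty")
    seen: set[int] = set()
    for chord in chord_table:
        if chord.chord_id in seen:
            raise ValueError(f"duplicate chord id {chord.chord_id} in chord table")
        seen.add(chord.chord_id)
    return [
        DesignCell(float(ioi), float(fb), chord)
        for ioi in sorted(ioi_set)
        for fb in sorted(feedback_set)
        for chord in sorted(chord_table, key=lambda c: c.chord_id)
    ]


@dataclass(frozen=True)
class TrialCondition:
    """Design-cell assignment of a single trial.

    ``n_lead_clicks`` metronome clicks play before participants join at the
    next click; ``n_sync_clicks`` clicks are tapped along with; the gong
    sounds ``n_cont_beats`` IOIs after the final click.
    """

    dyad_id: str
    trial_index: int
    ioi_ms: float
    feedback_ms: float
    chord_id: int
    n_lead_clicks: int = 4
    n_sync_clicks: int = 20
    n_cont_beats: int = 20

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        if self.chord_id not in _CHORD_BY_ID:
            raise ValueError(f"unknown chord_id {self.chord_id}")
        if self.ioi_ms not in IOI_SET:
            raise ValueError(f"ioi_ms {self.ioi_ms} not in design set {IOI_SET}")
        if self.feedback_ms not in FEEDBACK_SET:
            raise ValueError(
                f"feedback_ms {self.feedback_ms} not in design set {FEEDBACK_SET}"
            )
        if self.n_lead_clicks < 0 or self.n_sync_clicks < 1 or self.n_cont_beats < 1:
            raise ValueError("click/beat counts out of range")

    @property
    def chord(self) -> ChordAssignment:
        return _CHORD_BY_ID[self.chord_id]

    @property
    def consonance(self) -> Optional[str]:
        return self.chord.consonance

    @property
    def n_clicks(self) -> int:
        return self.n_lead_clicks + self.n_sync_clicks

    def click_times(self) -> list[float]:
        """Programmatic metronome onsets, exactly on the IOI grid."""
        return [i * self.ioi_ms for i in range(self.n_clicks)]

    @property
    def last_click_ms(self) -> float:
        return (self.n_clicks - 1) * self.ioi_ms

    @property
    def planned_gong_ms(self) -> float:
        return self.last_click_ms + self.n_cont_beats * self.ioi_ms


@dataclass
class TrialEvents:
    """All timestamped events of one trial, plus post-trial pleasure ratings."""

    condition: TrialCondition
    clicks: list[float]
    taps_a: list[float]
    taps_b: list[float]
    gong_ms: float
    rating_a: Optional[int] = None
    rating_b: Optional[int] = None

    def validate(self) -> None:
        """Enforce the event-model invariants; raise ``ValueError`` on breach."""
        ioi = self.condition.ioi_ms
        for i, (c0, c1) in enumerate(zip(self.clicks, self.clicks[1:])):
            if not math.isclose(c1 - c0, ioi, rel_tol=0, abs_tol=1e-6):
                raise ValueError(
                    f"clicks {i},{i + 1} spaced {c1 - c0} ms, expected {ioi}"
                )
        if self.clicks and self.gong_ms <= self.clicks[-1]:
            raise ValueError("gong must sound after the last click")
        for name, taps in (("A", self.taps_a), ("B", self.taps_b)):
            for i, (t0, t1) in enumerate(zip(taps, taps[1:])):
                if t1 <= t0:
                    raise ValueError(
                        f"taps of participant {name} not strictly increasing "
                        f"at position {i + 1} ({t0} -> {t1})"
                    )
        for name, rating in (("a", self.rating_a), ("b", self.rating_b)):
            if rating is not None and not 1 <= rating <= 10:
                raise ValueError(f"rating_{name}={rating} outside [1, 10]")

    @property
    def mean_rating(self) -> Optional[float]:
        if self.rating_a is None or self.rating_b is None:
            return None
        return (self.rating_a + self.rating_b) / 2.0


def assign_phase(
    event_time: float,
    clicks: Sequence[float],
    ioi_ms: float,
    gong_ms: float = math.inf,
) -> Optional[Phase]:
    """Label a pre-gong event as synchronization or continuation.

    The boundary is half an IOI after the final click, so a tap that lags the
    last click still counts as synchronization. Events after the gong are not
    phase-labelled: ``None`` is returned as an exclusion flag.
    """
    if not clicks:
        raise ValueError("clicks must be non-empty")
    if event_time > gong_ms:
        return None
    if event_time <= clicks[-1] + ioi_ms / 2.0:
        return Phase.SYNCHRONIZATION
    return Phase.CONTINUATION


class EventLogError(ValueError):
    """Raised when an event-log file violates the schema; carries the row."""

    def __init__(self, message: str, row: Optional[int] = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


EVENT_COLUMNS = [
    "dyad_id",
    "trial_index",
    "ioi_ms",
    "feedback_ms",
    "chord_id",
    "consonance",
    "participant",
    "event",
    "time_ms",
    "rating_value",
]

_VALID_EVENTS = {"click", "tap", "gong", "rating"}


def event_log_frame(trials: Iterable[TrialEvents]) -> pd.DataFrame:
    """Long-format event table: one row per click/tap/gong/rating."""
    rows: list[tuple] = []
    for trial in trials:
        cond = trial.condition
        base = (
            cond.dyad_id,
            cond.trial_index,
            cond.ioi_ms,
            cond.feedback_ms,
            cond.chord_id,
            cond.consonance or "",
        )
        for t in trial.clicks:
            rows.append(base + ("metronome", "click", t, ""))
        for t in trial.taps_a:
            rows.append(base + ("A", "tap", t, ""))
        for t in trial.taps_b:
            rows.append(base + ("B", "tap", t, ""))
        rows.append(base + ("gong", "gong", trial.gong_ms, ""))
        for who, rating in (("A", trial.rating_a), ("B", trial.rating_b)):
            if rating is not None:
                rows.append(base + (who, "rating", trial.gong_ms, rating))
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return frame.sort_values(
        ["dyad_id", "trial_index", "time_ms", "event", "participant"],
        kind="stable",
    ).reset_index(drop=True)


def write_event_log(trials: Iterable[TrialEvents], path) -> None:
    """Write trials to a UTF-8 TSV event log (see :data:`EVENT_COLUMNS`)."""
    frame = event_log_frame(trials)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_event_log(path) -> list[TrialEvents]:
    """Parse and validate a TSV event log back into :class:`TrialEvents`.

    Invalid files always raise :class:`EventLogError` with the offending
     1-based data-row number; they are never silently truncated.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype={"dyad_id": str}, keep_default_na=False, na_values=[]
    )
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise EventLogError(f"missing columns: {missing}")
    frame["_row"] = range(1, len(frame) + 1)

    bad = frame.loc[~frame["event"].isin(_VALID_EVENTS)]
    if len(bad):
        first = bad.iloc[0]
        raise EventLogError(
            f"unknown event type {first['event']!r}", row=int(first["_row"])
        )

    trials: list[TrialEvents] = []
    for (dyad, trial_idx), group in frame.groupby(
        ["dyad_id", "trial_index"], sort=True
    ):
        cond = TrialCondition(
            dyad_id=str(dyad),
            trial_index=int(trial_idx),
            ioi_ms=float(group["ioi_ms"].iloc[0]),
            feedback_ms=float(group["feedback_ms"].iloc[0]),
            chord_id=int(group["chord_id"].iloc[0]),
        )
        taps: dict[str, list[float]] = {"A": [], "B": []}
        for participant in ("A", "B"):
            sel = group[(group["event"] == "tap") & (group["participant"] == participant)]
            times = sel["time_ms"].astype(float).tolist()
            for i in range(1, len(times)):
                if times[i] <= times[i - 1]:
                    raise EventLogError(
                        f"non-monotone taps for participant {participant} in "
                        f"dyad {dyad} trial {trial_idx}",
                        row=int(sel["_row"].iloc[i]),
                    )
            taps[participant] = times
        clicks = (
            group.loc[group["event"] == "click", "time_ms"].astype(float).tolist()
        )
        gongs = group.loc[group["event"] == "gong", "time_ms"].astype(float)
        if len(gongs) != 1:
            raise EventLogError(
                f"dyad {dyad} trial {trial_idx} has {len(gongs)} gong events"
            )
        ratings: dict[str, Optional[int]] = {"A": None, "B": None}
        rating_rows = group[group["event"] == "rating"]
        for _, r in rating_rows.iterrows():
            value = int(float(r["rating_value"]))
            if not 1 <= value <= 10:
                raise EventLogError(
                    f"rating {value} outside [1, 10]", row=int(r["_row"])
                )
            ratings[str(r["participant"])] = value
        trial = TrialEvents(
            condition=cond,
            clicks=clicks,
            taps_a=taps["A"],
            taps_b=taps["B"],
            gong_ms=float(gongs.iloc[0]),
            rating_a=ratings["A"],
            rating_b=ratings["B"],
        )
        trial.validate()
        trials.append(trial)
    return trials


QUESTIONNAIRE_COLUMNS = [
    "participant_id",
    "dyad_id",
    "instrument",
    "item_index",
    "response",
]


def write_questionnaire_log(frame: pd.DataFrame, path) -> None:
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in frame.columns]
    if missing:
        raise EventLogError(f"questionnaire log missing columns: {missing}")
    frame[QUESTIONNAIRE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_questionnaire_log(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "dyad_id": str})
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in frame.columns]
    if missing:
        raise EventLogError(f"questionnaire log missing columns: {missing}")
    return frame
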