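"""Scoring of the study's self-report instruments and the pitch test.

Instruments: IOS (Inclusion of Other in Self, 7-step pictorial closeness
scale, expressed as a percentage), eBMRQ (extended Barcelona Music Reward
Questionnaire, 24 five-point items in six 4-item subscales), Gold-MSI
Musical Training (7 seven-point items, year-band responses mapped to 1-7)
and Perceptual Abilities (9 seven-point items), AQ (Autism Quotient, 50
four-option items scored binary against an agree/disagree key), and a
10-pair chord discrimination test.

Item-level keys (reversals, AQ agreement side, pitch answer key) ship as
editable JSON config files under ``dyadsync/instruments/``; the structural
constraints (item counts, score maxima 120 / 49 / 63 / 50 / 100%) are
enforced by the loader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .stats import one_sample_t

__all__ = [
    "InstrumentSpec",
    "load_instrument",
    "score_instrument",
    "score_ios",
    "score_pitch_test",
    "group_above_chance",
    "map_years_to_band",
    "score_participants",
    "dyad_sums",
    "PITCH_TEST_KEY",
    "AQ_AGREE_ITEMS",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative description of one instrument's items and scoring."""

    name: str
    kind: str  # likert | aq_binary | ios | pitch
    n_items: int
    response_min: int
    response_max: int
    reverse_items: tuple[int, ...] = ()
    subscales: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    agree_items: tuple[int, ...] = ()
    agree_responses: tuple[int, ...] = (1, 2)
    answer_key: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for item in self.reverse_items:
            if not 1 <= item <= self.n_items:
                raise ValueError(f"{self.name}: reverse item {item} out of range")
        if self.subscales:
            covered = sorted(i for items in self.subscales.values() for i in items)
            if covered != list(range(1, self.n_items + 1)):
                raise ValueError(f"{self.name}: subscales must partition the items")

    @property
    def max_score(self) -> int:
        if self.kind == "likert":
            return self.n_items * self.response_max
        if self.kind == "aq_binary":
            return self.n_items
        if self.kind == "ios":
            return 100
        if self.kind == "pitch":
            return self.n_items
        raise ValueError(f"unknown instrument kind {self.kind}")


def load_instrument(name: str) -> InstrumentSpec:
    """Load an instrument key file from the packaged config directory."""
    path = resources.files("dyadsync.instruments").joinpath(f"{name}.json")
    data = json.loads(path.read_text())
    return InstrumentSpec(
        name=data["name"],
        kind=data["kind"],
        n_items=data["n_items"],
        response_min=data["response_min"],
        response_max=data["response_max"],
        reverse_items=tuple(data.get("reverse_items", [])),
        subscales={k: tuple(v) for k, v in data.get("subscales", {}).items()},
        agree_items=tuple(data.get("agree_items", [])),
        agree_responses=tuple(data.get("agree_responses", [1, 2])),
        answer_key=tuple(data.get("answer_key", [])),
    )


_SPEC_CACHE: dict[str, InstrumentSpec] = {}


def _spec(name: str) -> InstrumentSpec:
    if name not in _SPEC_CACHE:
        _SPEC_CACHE[name] = load_instrument(name)
    return _SPEC_CACHE[name]


PITCH_TEST_KEY: tuple[int, ...] = _spec("pitch_test").answer_key
AQ_AGREE_ITEMS: tuple[int, ...] = _spec("aq").agree_items


def _validate_responses(responses: Sequence[int], spec: InstrumentSpec) -> None:
    if len(responses) != spec.n_items:
        raise ValueError(
            f"{spec.name}: expected {spec.n_items} responses, got {len(responses)}"
        )
    for i, r in enumerate(responses, start=1):
        if r is None or not spec.response_min <= r <= spec.response_max:
            raise ValueError(f"{spec.name}: item {i} response {r!r} out of range")


def score_instrument(responses: Sequence[int], spec: InstrumentSpec) -> dict[str, int]:
    """Score one participant's responses; returns total plus any subscales.

    Likert instruments sum the (per-item reversed where keyed) responses;
    the AQ scores one point per item whose response side matches the item's
    agree/disagree key, collapsing "slightly" and "definitely".
    """
    _validate_responses(responses, spec)
    if spec.kind == "likert":
        lo, hi = spec.response_min, spec.response_max
        values = [
            (lo + hi - r) if item in spec.reverse_items else r
            for item, r in enumerate(responses, start=1)
        ]
        out = {"total": sum(values)}
        for name, items in spec.subscales.items():
            out[name] = sum(values[i - 1] for i in items)
        return out
    if spec.kind == "aq_binary":
        agree = set(spec.agree_items)
        agree_side = set(spec.agree_responses)
        total = 0
        for item, r in enumerate(responses, start=1):
            responded_agree = r in agree_side
            total += int(responded_agree == (item in agree))
        return {"total": total}
    raise ValueError(f"score_instrument does not handle kind {spec.kind!r}")


def score_ios(response_level: int, n_levels: int = 7) -> float:
    """Map a circle-overlap step to percent: (level - 1)/(n_levels - 1) * 100."""
    if not 1 <= response_level <= n_levels:
        raise ValueError(f"IOS level {response_level} outside [1, {n_levels}]")
    return (response_level - 1) / (n_levels - 1) * 100.0


def score_pitch_test(
    responses: Sequence[int], answer_key: Sequence[int] = PITCH_TEST_KEY
) -> int:
    """Number of correct same/different judgements (0-10)."""
    if len(responses) != len(answer_key):
        raise ValueError(
            f"expected {len(answer_key)} pitch-test responses, got {len(responses)}"
        )
    return int(sum(int(r == k) for r, k in zip(responses, answer_key)))


def group_above_chance(counts: Sequence[float], chance: float = 5.0):
    """One-sample t of pitch-test correct counts against the chance level."""
    return one_sample_t(counts, mu0=chance)


_YEAR_BANDS = (0, 1, 2, 3, 5, 9)  # upper edges; above the last -> band 7


def map_years_to_band(years: float) -> int:
    """Map years of practice to the 1-7 training band (0,1,2,3,4-5,6-9,10+)."""
    if years < 0:
        raise ValueError("years must be >= 0")
    for band, upper in enumerate(_YEAR_BANDS, start=1):
        if years <= upper:
            return band
    return 7


def score_participants(responses: pd.DataFrame) -> pd.DataFrame:
    """Score every participant in a long questionnaire table.

    Expects the questionnaire TSV schema (participant_id, dyad_id,
    instrument, item_index, response) and returns one row per participant
    with ios_pre/ios_post/ios_change (percent), ebmrq total and subscales,
    gmsi_mt, gmsi_pa, aq, and pitch_correct.
    """
    rows = []
    for (pid, dyad), group in responses.groupby(["participant_id", "dyad_id"]):
        def items(instrument: str) -> list[int]:
            sel = group[group["instrument"] == instrument].sort_values("item_index")
            return sel["response"].astype(int).tolist()

        row: dict = {"participant_id": pid, "dyad_id": dyad}
        ios_pre = items("ios_pre")
        ios_post = items("ios_post")
        if ios_pre:
            row["ios_pre"] = score_ios(ios_pre[0])
        if ios_post:
            row["ios_post"] = score_ios(ios_post[0])
        if ios_pre and ios_post:
            row["ios_change"] = row["ios_post"] - row["ios_pre"]
        for name in ("ebmrq", "gmsi_mt", "gmsi_pa"):
            resp = items(name)
            if resp:
                scores = score_instrument(resp, _spec(name))
                row[name] = scores["total"]
                if name == "ebmrq":
                    for sub, value in scores.items():
                        if sub != "total":
                            row[f"ebmrq_{sub}"] = value
        aq = items("aq")
        if aq:
            row["aq"] = score_instrument(aq, _spec("aq"))["total"]
        pitch = items("pitch_test")
        if pitch:
            row["pitch_correct"] = score_pitch_test(pitch)
        rows.append(row)
    return pd.DataFrame(rows)


DYAD_SUM_INSTRUMENTS = ("ios_pre", "ebmrq", "aq", "gmsi_mt", "gmsi_pa")


def dyad_sums(
    participant_scores: pd.DataFrame,
    instruments: Sequence[str] = DYAD_SUM_INSTRUMENTS,
) -> pd.DataFrame:
    """Per-dyad predictor table: member A + member B score per instrument.

    Raises when a dyad is missing a member's score for any requested
    instrument; the design has exactly two scored members per dyad.
    """
    out = []
    for dyad, group in participant_scores.groupby("dyad_id"):
        if len(group) != 2:
            raise ValueError(f"dyad {dyad} has {len(group)} scored members, expected 2")
        row: dict = {"dyad_id": dyad}
        for name in instruments:
            if name not in group.columns or group[name].isna().any():
                raise ValueError(f"dyad {dyad} missing {name} score for a member")
            row[f"{name}_sum"] = float(group[name].sum())
        out.append(row)
    return pd.DataFrame(out)
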