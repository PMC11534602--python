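"""Generative simulator of (dyadic) synchronization-continuation tapping.

The timing model is a linear phase-correction loop wrapped around
two-level Wing-Kristofferson noise (central timekeeper variance plus motor
implementation variance that enters as a first difference), extended with a
symmetric partner-coupling term. For agent i with partner j, the next tap in
the synchronization phase is

    t_i(n+1) = t_i(n) + IOI - alpha_i * A_i(n) - beta_i' * (t_i(n) - t_j(n))
               + e_tk(n) + e_m(n+1) - e_m(n)

where A_i(n) is the signed asynchrony to the scheduled metronome click,
e_tk ~ N(0, sigma_tk^2), e_m ~ N(0, sigma_m^2), and beta_i' is the coupling
gain, multiplied by ``beta_gain_consonant`` on consonant trials (consonance
tightens mutual coupling). The continuation phase drops the alpha term and
replaces the IOI by the agent's internal interval estimate, compounded by a
per-interval tempo drift.

For an uncoupled agent (beta = 0) the asynchrony follows the ARMA recursion
A(n+1) = (1-alpha) A(n) + e_tk(n) + e_m(n+1) - e_m(n) with stationary
variance (sigma_tk^2 + 2*alpha*sigma_m^2) / (alpha * (2 - alpha)), which
serves as a closed-form oracle for the simulator.

Pleasure ratings are drawn per participant from a normal around a
consonance-dependent mean, optionally shifted by the trial's realized
synchrony, then rounded and clipped to the 1-10 scale.

Randomness is fully reproducible: a master seed spawns one substream per
dyad, which spawns one substream per trial (numpy ``SeedSequence``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .events import (
    CONSONANT,
    DesignCell,
    TrialCondition,
    TrialEvents,
    build_condition_grid,
)
from .questionnaires import AQ_AGREE_ITEMS, PITCH_TEST_KEY

__all__ = [
    "AgentParams",
    "EffectConfig",
    "SimulationError",
    "stationary_asynchrony_variance",
    "simulate_dyad_trial",
    "simulate_individual_trial",
    "simulate_experiment",
    "simulate_questionnaires",
]

#: Reference synchrony (ms) around which the rating-synchrony coupling pivots;
#: roughly the observed scale of mean absolute tap differences.
RATING_SYNC_CENTER_LOG = math.log(50.0)


class SimulationError(RuntimeError):
    """Raised when a trial's dynamics diverge (unstable configuration)."""


@dataclass(frozen=True)
class AgentParams:
    """Timing parameters of one tapping agent.

    alpha : metronome phase-correction gain, stable in (0, 2)
    beta : partner-coupling gain (>= 0)
    sigma_tk : timekeeper noise SD (ms)
    sigma_m : motor noise SD (ms)
    tempo_drift : per-interval multiplicative drift in continuation
    """

    alpha: float = 0.5
    beta: float = 0.15
    sigma_tk: float = 25.0
    sigma_m: float = 12.0
    tempo_drift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 2.0:
            raise ValueError(f"alpha={self.alpha} outside the stable range (0, 2)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma_tk < 0 or self.sigma_m < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class EffectConfig:
    """Consonance-dependent modulations of coupling and pleasure.

    ``beta_gain_consonant`` = 1 together with equal rating means yields a
    null world with no consonance effect anywhere.
    """

    beta_gain_consonant: float = 1.5
    rating_mu_consonant: float = 6.4
    rating_mu_dissonant: float = 6.0
    rating_sigma: float = 1.5
    rating_sync_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.beta_gain_consonant < 1:
            raise ValueError("beta_gain_consonant must be >= 1")
        for mu in (self.rating_mu_consonant, self.rating_mu_dissonant):
            if not 1 <= mu <= 10:
                raise ValueError("rating means must lie in [1, 10]")
        if self.rating_sigma < 0:
            raise ValueError("rating_sigma must be >= 0")


NULL_EFFECTS = EffectConfig(
    beta_gain_consonant=1.0, rating_mu_consonant=6.0, rating_mu_dissonant=6.0
)


def stationary_asynchrony_variance(alpha: float, sigma_tk: float, sigma_m: float) -> float:
    """Closed-form stationary variance of the uncoupled asynchrony process."""
    return (sigma_tk**2 + 2.0 * alpha * sigma_m**2) / (alpha * (2.0 - alpha))


def _draw_rating(rng: np.random.Generator, mu: float, sigma: float) -> int:
    value = round(rng.normal(mu, sigma))
    return int(min(10, max(1, value)))


def simulate_dyad_trial(
    condition: TrialCondition,
    params_a: AgentParams,
    params_b: AgentParams,
    effects: EffectConfig = EffectConfig(),
    rng: Optional[np.random.Generator] = None,
    rng_seed: Optional[int] = None,
    start_offset_a: float = 0.0,
    start_offset_b: float = 0.0,
) -> TrialEvents:
    """Simulate one dyadic trial; fully reproducible from the seed.

    Both agents tap in lockstep from the fifth metronome click through the
    continuation phase; taps falling after the gong are not emitted.
    ``start_offset_*`` adds a deterministic shift to the first tap (useful
    for studying the correction dynamics from a known initial asynchrony).
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    clicks = condition.click_times()
    ioi = condition.ioi_ms
    gong = condition.planned_gong_ms
    lead = condition.n_lead_clicks
    n_sync = condition.n_sync_clicks
    n_steps = n_sync + condition.n_cont_beats

    gain = effects.beta_gain_consonant if condition.consonance == CONSONANT else 1.0
    beta_a = params_a.beta * gain
    beta_b = params_b.beta * gain

    # pre-drawn noise keeps the draw order independent of the dynamics
    etk_a = rng.normal(0.0, params_a.sigma_tk, n_steps)
    em_a = rng.normal(0.0, params_a.sigma_m, n_steps + 1)
    etk_b = rng.normal(0.0, params_b.sigma_tk, n_steps)
    em_b = rng.normal(0.0, params_b.sigma_m, n_steps + 1)

    ta = clicks[lead] + start_offset_a + rng.normal(0.0, params_a.sigma_tk)
    tb = clicks[lead] + start_offset_b + rng.normal(0.0, params_b.sigma_tk)
    interval_a = interval_b = ioi
    taps_a = [ta]
    taps_b = [tb]
    for step in range(n_steps - 1):
        in_sync = step < n_sync - 1  # current tap has a scheduled click
        if in_sync:
            sched = clicks[lead + step]
            asyn_a = ta - sched
            asyn_b = tb - sched
            if abs(asyn_a) > 5 * ioi or abs(asyn_b) > 5 * ioi:
                raise SimulationError(
                    f"divergence in dyad {condition.dyad_id} "
                    f"trial {condition.trial_index} at step {step}"
                )
            corr_a = params_a.alpha * asyn_a
            corr_b = params_b.alpha * asyn_b
        else:
            interval_a *= 1.0 + params_a.tempo_drift
            interval_b *= 1.0 + params_b.tempo_drift
            corr_a = corr_b = 0.0
        next_a = (
            ta + interval_a - corr_a - beta_a * (ta - tb)
            + etk_a[step] + em_a[step + 1] - em_a[step]
        )
        next_b = (
            tb + interval_b - corr_b - beta_b * (tb - ta)
            + etk_b[step] + em_b[step + 1] - em_b[step]
        )
        ta, tb = next_a, next_b
        taps_a.append(ta)
        taps_b.append(tb)

    # realized synchrony of the whole trial drives the optional rating term
    diffs = [abs(x - y) for x, y in zip(taps_a, taps_b)]
    mean_diff = sum(diffs) / len(diffs)
    sync_shift = 0.0
    if effects.rating_sync_weight and mean_diff > 0:
        sync_shift = effects.rating_sync_weight * (
            math.log(mean_diff) - RATING_SYNC_CENTER_LOG
        )
    mu = (
        effects.rating_mu_consonant
        if condition.consonance == CONSONANT
        else effects.rating_mu_dissonant
    )
    rating_a = _draw_rating(rng, mu - sync_shift, effects.rating_sigma)
    rating_b = _draw_rating(rng, mu - sync_shift, effects.rating_sigma)

    trial = TrialEvents(
        condition=condition,
        clicks=clicks,
        taps_a=sorted(t for t in taps_a if t <= gong),
        taps_b=sorted(t for t in taps_b if t <= gong),
        gong_ms=gong,
        rating_a=rating_a,
        rating_b=rating_b,
    )
    trial.validate()
    return trial


def simulate_individual_trial(
    condition: TrialCondition,
    params: AgentParams,
    rng: Optional[np.random.Generator] = None,
    rng_seed: Optional[int] = None,
) -> TrialEvents:
    """Single-agent synchronization-continuation trial (no partner, no rating).

    The lone agent's taps are stored as participant A; participant B is empty.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    solo = replace(params, beta=0.0)
    ghost = AgentParams(alpha=1.0, beta=0.0, sigma_tk=0.0, sigma_m=0.0)
    trial = simulate_dyad_trial(
        condition, solo, ghost, NULL_EFFECTS, rng=rng
    )
    trial.taps_b = []
    trial.rating_a = None
    trial.rating_b = None
    return trial


def _jitter_params(
    params: AgentParams, jitter: float, rng: np.random.Generator
) -> AgentParams:
    """Lognormal per-dyad jitter on every positive parameter."""
    if jitter <= 0:
        return params

    def lj(x: float) -> float:
        return float(x * rng.lognormal(0.0, jitter)) if x > 0 else x

    alpha = min(1.95, lj(params.alpha))
    return AgentParams(
        alpha=alpha,
        beta=lj(params.beta),
        sigma_tk=lj(params.sigma_tk),
        sigma_m=lj(params.sigma_m),
        tempo_drift=params.tempo_drift,
    )


def simulate_experiment(
    n_dyads: int,
    params: AgentParams = AgentParams(),
    effects: EffectConfig = EffectConfig(),
    design: Optional[Sequence[DesignCell]] = None,
    master_seed: int = 0,
    param_jitter: float = 0.1,
    glitch_rate: float = 0.0,
) -> tuple[list[TrialEvents], dict]:
    """Simulate a full multi-dyad experiment.

    Trial order is randomized independently per dyad; agent parameters get
    optional lognormal per-dyad jitter. Returns the trials plus a
    ground-truth sidecar (per-dyad parameters, effect configuration, seeds)
    for parameter/effect-recovery checks.
    """
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    if design is None:
        design = build_condition_grid()
    master = np.random.SeedSequence(master_seed)
    dyad_seeds = master.spawn(n_dyads)

    trials: list[TrialEvents] = []
    truth: dict = {
        "master_seed": master_seed,
        "effects": effects,
        "param_template": params,
        "dyads": {},
    }
    for d, dyad_seq in enumerate(dyad_seeds):
        dyad_id = f"dyad{d + 1:02d}"
        dyad_rng = np.random.default_rng(dyad_seq)
        pa = _jitter_params(params, param_jitter, dyad_rng)
        pb = _jitter_params(params, param_jitter, dyad_rng)
        order = dyad_rng.permutation(len(design))
        truth["dyads"][dyad_id] = {"params_a": pa, "params_b": pb}
        trial_seqs = dyad_seq.spawn(len(design))
        for trial_index, cell_idx in enumerate(order, start=1):
            cell = design[cell_idx]
            cond = TrialCondition(
                dyad_id=dyad_id,
                trial_index=trial_index,
                ioi_ms=cell.ioi_ms,
                feedback_ms=cell.feedback_ms,
                chord_id=cell.chord.chord_id,
            )
            trial_rng = np.random.default_rng(trial_seqs[trial_index - 1])
            trial = simulate_dyad_trial(cond, pa, pb, effects, rng=trial_rng)
            if glitch_rate > 0 and trial_rng.random() < glitch_rate:
                if trial_rng.random() < 0.5:
                    trial.taps_a = []
                else:
                    trial.taps_b = []
            trials.append(trial)
    return trials, truth


# --- questionnaire generation ------------------------------------------------

# per-item response models emulating the observed score distributions:
# (instrument, n_items, response range, per-participant trait SD)
_LIKERT_SPECS = {
    "ebmrq": (24, 1, 5, 3.8, 0.45),  # item mean ~3.8 -> totals ~91
    "gmsi_mt": (7, 1, 7, 1.9, 0.9),  # non-musicians: low training
    "gmsi_pa": (9, 1, 7, 5.0, 0.6),
}


def simulate_questionnaires(
    dyad_ids: Sequence[str],
    master_seed: int = 0,
    ios_shift: float = 1.2,
) -> pd.DataFrame:
    """Synthetic questionnaire/item responses for every participant.

    Emulates non-musician adults: moderate music-reward sensitivity, low
    musical training, high perceptual abilities, low-to-moderate autistic
    traits, good pitch discrimination, and closeness that increases from the
    pre to the post measurement (``ios_shift`` levels on the 7-step scale).
    Returns the long questionnaire table (one row per item response).
    """
    rng = np.random.default_rng(np.random.SeedSequence((master_seed, 815)))
    rows: list[tuple] = []
    for dyad_id in dyad_ids:
        for member in ("A", "B"):
            pid = f"{dyad_id}{member}"

            def emit(instrument: str, item: int, response: int) -> None:
                rows.append((pid, dyad_id, instrument, item, response))

            ios_pre = int(np.clip(round(rng.normal(3.3, 1.8)), 1, 7))
            ios_post = int(np.clip(round(ios_pre + rng.normal(ios_shift, 1.2)), 1, 7))
            emit("ios_pre", 1, ios_pre)
            emit("ios_post", 1, ios_post)

            for name, (n_items, lo, hi, mu, trait_sd) in _LIKERT_SPECS.items():
                trait = rng.normal(mu, trait_sd)
                for item in range(1, n_items + 1):
                    r = int(np.clip(round(rng.normal(trait, 1.0)), lo, hi))
                    emit(name, item, r)

            # AQ: 4-option items; trait = probability of answering on the
            # keyed (autistic-like) side, low in a typical sample. Response
            # options 1-2 are the agree side, 3-4 the disagree side; the
            # instrument key decides which side scores the point.
            p_keyed = float(np.clip(rng.normal(0.3, 0.08), 0.02, 0.9))
            for item in range(1, 51):
                keyed = rng.random() < p_keyed
                on_agree_side = (item in AQ_AGREE_ITEMS) == keyed
                base = int(rng.integers(1, 3))  # slightly vs definitely
                emit("aq", item, base if on_agree_side else base + 2)

            # pitch test: 1 = "different", 0 = "same"; ~9/10 correct
            for item, key in enumerate(PITCH_TEST_KEY, start=1):
                correct = rng.random() < 0.9
                emit("pitch_test", item, key if correct else 1 - key)
    return pd.DataFrame(
        rows,
        columns=["participant_id", "dyad_id", "instrument", "item_index", "response"],
    )
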