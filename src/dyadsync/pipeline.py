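"""End-to-end pipeline: simulate (or load) -> preprocess -> analyze -> report.

A run is fully determined by its configuration and master seed: the manifest
written alongside the results records both, plus package versions, so any
output bundle can be regenerated byte-identically. Every exclusion applied
during preprocessing (glitch trials, post-gong taps, over-threshold pairs)
is logged with counts and percentages of the respective totals.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import (
    TrialEvents,
    build_condition_grid,
    read_event_log,
    read_questionnaire_log,
    write_event_log,
    write_questionnaire_log,
)
from .preprocess import detect_glitch_trial, trial_measures_frame
from .questionnaires import dyad_sums, group_above_chance, score_participants
from .simulate import (
    AgentParams,
    EffectConfig,
    simulate_experiment,
    simulate_questionnaires,
)
from .stats import (
    aggregate_cells,
    consonance_effect,
    correlate,
    one_sample_t,
    pleasure_slope,
    rm_anova,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    # either simulate ...
    simulate: bool = True
    n_dyads: int = 21
    params: AgentParams = field(default_factory=AgentParams)
    effects: EffectConfig = field(default_factory=EffectConfig)
    param_jitter: float = 0.1
    glitch_rate: float = 0.005
    # ... or load from logs
    event_log: Optional[str] = None
    questionnaire_log: Optional[str] = None
    # analysis toggles
    slope_convention: str = "neg_log"
    sphericity_correction: bool = False
    mutual_matching: bool = False
    master_seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "params" in raw and isinstance(raw["params"], dict):
            raw["params"] = AgentParams(**raw["params"])
        if "effects" in raw and isinstance(raw["effects"], dict):
            raw["effects"] = EffectConfig(**raw["effects"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def participant_rating_frame(trials: list[TrialEvents]) -> pd.DataFrame:
    """One row per participant per trial with the pleasure rating."""
    rows = []
    for trial in trials:
        cond = trial.condition
        for member, rating in (("A", trial.rating_a), ("B", trial.rating_b)):
            if rating is None:
                continue
            rows.append(
                {
                    "participant_id": f"{cond.dyad_id}{member}",
                    "dyad_id": cond.dyad_id,
                    "consonance": cond.consonance,
                    "ioi_ms": cond.ioi_ms,
                    "feedback_ms": cond.feedback_ms,
                    "rating": rating,
                }
            )
    return pd.DataFrame(rows)


def participant_measures_long(measures: pd.DataFrame) -> pd.DataFrame:
    """Reshape per-trial A/B columns into one row per participant per trial."""
    rows = []
    for _, row in measures.iterrows():
        for member in ("a", "b"):
            entry = {
                "participant_id": f"{row['dyad_id']}{member.upper()}",
                "dyad_id": row["dyad_id"],
                "trial_index": row["trial_index"],
                "consonance": row["consonance"],
                "ioi_ms": row["ioi_ms"],
                "feedback_ms": row["feedback_ms"],
                "phase": row["phase"],
            }
            for stem in ("mean_signed_ms", "sd_signed_ms", "mean_iti_ms", "sd_iti_ms"):
                col = f"{stem}_{member}"
                if col in row.index:
                    entry[stem] = row[col]
            rows.append(entry)
    return pd.DataFrame(rows)


def exclusion_report(trials: list[TrialEvents], measures: pd.DataFrame) -> dict:
    """Counts and percentages for every exclusion rule."""
    n_trials = len(trials)
    n_glitch = sum(detect_glitch_trial(t) for t in trials)
    used = int(measures["n_pairs_used"].sum())
    post_gong = int(measures["n_excluded_post_gong"].sum())
    over = int(measures["n_excluded_over_threshold"].sum())
    total_pairs = used + post_gong + over
    pct = lambda k, n: round(100.0 * k / n, 3) if n else 0.0
    return {
        "n_trials": n_trials,
        "glitch_trials": n_glitch,
        "glitch_trials_pct": pct(n_glitch, n_trials),
        "pairs_total": total_pairs,
        "pairs_used": used,
        "pairs_excluded_post_gong": post_gong,
        "pairs_excluded_post_gong_pct": pct(post_gong, total_pairs),
        "pairs_excluded_over_threshold": over,
        "pairs_excluded_over_threshold_pct": pct(over, total_pairs),
    }


def _anova_or_error(stage: str, grid, value, factors, unit, gg=False):
    try:
        return rm_anova(grid, value, factors, unit, sphericity_correction=gg)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc


def analyze(
    trials: list[TrialEvents],
    measures: pd.DataFrame,
    questionnaires: Optional[pd.DataFrame],
    slope_convention: str = "neg_log",
    sphericity_correction: bool = False,
) -> dict:
    """All inferential analyses; returns a dict of tables and statistics."""
    gg = sphericity_correction
    results: dict = {}
    interpersonal = measures[~measures["glitch"]]

    # pleasure: within-participant consonance x ioi x feedback ANOVA
    ratings = participant_rating_frame(trials)
    if len(ratings):
        grid = aggregate_cells(
            ratings, "rating", ["consonance", "ioi_ms", "feedback_ms"], "participant_id"
        )
        results["anova_pleasure"] = _anova_or_error(
            "analyze.pleasure", grid, "rating",
            ["consonance", "ioi_ms", "feedback_ms"], "participant_id", gg,
        )

    # interpersonal synchronization: within-dyad 4-factor ANOVA on log means
    grid = aggregate_cells(
        interpersonal, "log_mean_abs_diff",
        ["consonance", "ioi_ms", "feedback_ms", "phase"], "dyad_id",
    )
    results["cell_means_interpersonal"] = grid
    results["anova_interpersonal"] = _anova_or_error(
        "analyze.interpersonal", grid, "log_mean_abs_diff",
        ["consonance", "ioi_ms", "feedback_ms", "phase"], "dyad_id", gg,
    )

    # individual precision: sync-phase signed diffs, continuation ITIs
    indiv = participant_measures_long(measures)
    sync = indiv[indiv["phase"] == "synchronization"]
    cont = indiv[indiv["phase"] == "continuation"]
    for key, frame, value in (
        ("anova_signed_mean", sync, "mean_signed_ms"),
        ("anova_signed_sd", sync, "sd_signed_ms"),
        ("anova_iti_mean", cont, "mean_iti_ms"),
        ("anova_iti_sd", cont, "sd_iti_ms"),
    ):
        grid = aggregate_cells(
            frame, value, ["consonance", "ioi_ms", "feedback_ms"], "participant_id"
        )
        results[key] = _anova_or_error(
            f"analyze.{key}", grid, value,
            ["consonance", "ioi_ms", "feedback_ms"], "participant_id", gg,
        )

    # per-trial pleasure-synchrony slopes (one row per trial)
    trial_level = interpersonal.drop_duplicates(["dyad_id", "trial_index"])
    slope = pleasure_slope(trial_level, convention=slope_convention)
    results["slopes"] = slope.slopes
    results["slope_group"] = {
        "mean_slope": slope.mean_slope,
        "sd_slope": slope.sd_slope,
        "t": slope.t,
        "df": slope.df,
        "p": slope.p,
        "convention": slope.convention,
    }

    # dyad consonance effects
    effects = consonance_effect(trial_level)
    results["consonance_effects"] = effects

    # questionnaires and correlations
    if questionnaires is not None and len(questionnaires):
        scores = score_participants(questionnaires)
        results["participant_scores"] = scores
        sums = dyad_sums(scores)
        results["dyad_sums"] = sums
        dyad_sync = (
            trial_level.groupby("dyad_id")["trial_log_mean_abs_diff"]
            .mean()
            .rename("mean_log_abs_diff")
            .reset_index()
        )
        joined = effects.merge(sums, on="dyad_id").merge(dyad_sync, on="dyad_id")
        corr_rows = []
        for target, preds in (
            ("consonance_effect", ["ebmrq_sum", "ios_pre_sum"]),
            (
                "mean_log_abs_diff",
                ["ios_pre_sum", "ebmrq_sum", "aq_sum", "gmsi_mt_sum", "gmsi_pa_sum"],
            ),
        ):
            for pred in preds:
                r, p, n = correlate(joined[pred], joined[target])
                corr_rows.append(
                    {"outcome": target, "predictor": pred, "r": r, "p": p, "n": n}
                )
        results["correlations"] = pd.DataFrame(corr_rows)

        if "pitch_correct" in scores.columns and scores["pitch_correct"].notna().all():
            t, df, p = group_above_chance(scores["pitch_correct"])
            results["pitch_test"] = {
                "mean_correct": float(scores["pitch_correct"].mean()),
                "sd_correct": float(scores["pitch_correct"].std(ddof=1)),
                "t_vs_chance": t,
                "df": df,
                "p": p,
            }
        if {"ios_pre", "ios_post"} <= set(scores.columns):
            t, df, p = one_sample_t(scores["ios_change"], 0.0)
            results["ios_change"] = {
                "mean_change_pct": float(scores["ios_change"].mean()),
                "t": t,
                "df": df,
                "p": p,
            }
    return results


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns the JSON-serializable summary (also written to
    ``summary.json``). Any stage error aborts with a stage-tagged message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: data -------------------------------------------------------
    if config.simulate:
        try:
            trials, truth = simulate_experiment(
                config.n_dyads,
                params=config.params,
                effects=config.effects,
                master_seed=config.master_seed,
                param_jitter=config.param_jitter,
                glitch_rate=config.glitch_rate,
            )
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        write_event_log(trials, out / "events.tsv")
        qframe = simulate_questionnaires(
            sorted({t.condition.dyad_id for t in trials}),
            master_seed=config.master_seed,
        )
        write_questionnaire_log(qframe, out / "questionnaires.tsv")
        truth_json = {
            "master_seed": truth["master_seed"],
            "effects": dataclasses.asdict(truth["effects"]),
            "param_template": dataclasses.asdict(truth["param_template"]),
            "dyads": {
                d: {k: dataclasses.asdict(v) for k, v in entry.items()}
                for d, entry in truth["dyads"].items()
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    else:
        if not config.event_log:
            raise PipelineError("load", "no event_log path and simulate=false")
        try:
            trials = read_event_log(config.event_log)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        qframe = (
            read_questionnaire_log(config.questionnaire_log)
            if config.questionnaire_log
            else None
        )

    # --- stage: preprocess -------------------------------------------------
    try:
        measures = trial_measures_frame(trials, mutual=config.mutual_matching)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    measures.to_csv(out / "trial_measures.tsv", sep="\t", index=False)
    exclusions = exclusion_report(trials, measures)

    # --- stage: analyze ----------------------------------------------------
    results = analyze(
        trials,
        measures,
        qframe,
        slope_convention=config.slope_convention,
        sphericity_correction=config.sphericity_correction,
    )

    # --- stage: report -----------------------------------------------------
    summary: dict = {"exclusions": exclusions}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.tsv", sep="\t", index=False)
            if key.startswith("anova_") or key in ("correlations",):
                summary[key] = value.to_dict(orient="records")
        else:
            summary[key] = value
    manifest = {
        "dyadsync_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "master_seed": config.master_seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
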