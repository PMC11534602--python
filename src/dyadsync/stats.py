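"""Repeated-measures inference for fully-within tapping designs.

The central routine is a classical univariate repeated-measures ANOVA for
complete, balanced, fully-within designs (every unit observed once in every
cell). Sums of squares come from the Moebius (inclusion-exclusion) effect
decomposition of the cell-means array; each design effect is tested against
its interaction with the unit factor, F = MS_effect / MS_(effect x unit).
Effect sizes are generalized eta squared for fully-within designs
(Olejnik-Algina): SS_effect divided by SS_effect plus the sum of every
unit-related (subject and subject-interaction) sum of squares. No sphericity
correction is applied by default; Greenhouse-Geisser adjustment is available
behind a flag.

The module also provides the dyad-level derived statistics of the pipeline:
per-dyad pleasure-synchrony regression slopes with a group t-test, the dyad
consonance effect (consonant minus dissonant mean log synchrony), Holm
step-down adjustment, Pearson correlation, and a one-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_cells",
    "ss_decomposition",
    "rm_anova",
    "holm_posthoc",
    "pleasure_slope",
    "consonance_effect",
    "correlate",
    "one_sample_t",
    "SlopeResult",
]


def aggregate_cells(
    trial_measures: pd.DataFrame,
    value: str,
    factors: Sequence[str],
    unit: str,
) -> pd.DataFrame:
    """Per-unit cell means over a fully-crossed factor grid.

    Returns a long dataframe (unit, factor levels, cell mean). Every design
    cell must contain at least one usable (non-null) trial for every unit;
    a missing cell is a hard error listing the offending (unit, cell) pairs,
    because the design is complete by construction.
    """
    data = trial_measures.dropna(subset=[value])
    grouped = (
        data.groupby([unit, *factors], observed=True)[value].mean().reset_index()
    )
    levels = [sorted(data[f].unique()) for f in factors]
    units = sorted(data[unit].unique())
    expected = len(units) * int(np.prod([len(lv) for lv in levels]))
    if len(grouped) != expected:
        full = pd.MultiIndex.from_product([units, *levels], names=[unit, *factors])
        have = pd.MultiIndex.from_frame(grouped[[unit, *factors]])
        missing = full.difference(have)
        raise ValueError(
            f"incomplete design: {len(missing)} empty cell(s), e.g. "
            f"{list(missing[:5])}"
        )
    return grouped.sort_values([unit, *factors]).reset_index(drop=True)


def ss_decomposition(arr: np.ndarray) -> dict[frozenset, float]:
    """Moebius sum-of-squares decomposition of a balanced data array.

    ``arr`` has one axis per factor (axis 0 conventionally the unit).
    Returns SS for every non-empty axis subset; SS(total about the grand
    mean) equals the sum of all terms.
    """
    naxes = arr.ndim
    grand = arr.mean()
    effects: dict[frozenset, np.ndarray] = {}
    ss: dict[frozenset, float] = {}
    subsets = [
        frozenset(c)
        for size in range(1, naxes + 1)
        for c in combinations(range(naxes), size)
    ]
    for subset in subsets:
        collapse = tuple(i for i in range(naxes) if i not in subset)
        margin = arr.mean(axis=collapse, keepdims=True) - grand
        for sub in effects:
            if sub < subset:
                margin = margin - effects[sub]
        effects[subset] = margin
        ss[subset] = float((margin**2).sum() * (arr.size / margin.size))
    return ss


def _gg_epsilon(cells: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of per-unit cell scores."""
    k = cells.shape[1]
    if k < 2:
        return 1.0
    cov = np.cov(cells, rowvar=False)
    centered = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * (centered**2).sum()
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def rm_anova(
    grid: pd.DataFrame,
    value: str,
    factors: Sequence[str],
    unit: str,
    sphericity_correction: bool = False,
) -> pd.DataFrame:
    """Fully-within repeated-measures ANOVA on a complete cell-means grid.

    Parameters
    ----------
    grid : long dataframe as produced by :func:`aggregate_cells` (one row
        per unit x cell, every cell present for every unit).
    factors : within-unit design factors; every main effect and interaction
        is tested.
    sphericity_correction : apply Greenhouse-Geisser df adjustment to the
        p-values of effects with numerator df > 1.

    Returns the ANOVA table with one row per effect: F, exact dfs, p, ηG²,
    and the underlying sums of squares.
    """
    factors = list(factors)
    units = sorted(grid[unit].unique())
    if len(units) < 2:
        raise ValueError("need at least 2 units for a repeated-measures ANOVA")
    levels = {f: sorted(grid[f].unique()) for f in factors}
    wide = grid.set_index([unit, *factors])[value].sort_index()
    shape = (len(units), *(len(levels[f]) for f in factors))
    if len(wide) != int(np.prod(shape)):
        raise ValueError("grid is not a complete crossing of unit and factors")
    arr = wide.to_numpy().reshape(shape)

    ss = ss_decomposition(arr)
    dims = dict(enumerate(shape))
    df = {s: int(np.prod([dims[i] - 1 for i in s])) for s in ss}
    unit_terms = [s for s in ss if 0 in s]
    ss_unit_total = sum(ss[s] for s in unit_terms)

    rows = []
    effect_subsets = [
        frozenset(c)
        for size in range(1, len(factors) + 1)
        for c in combinations(range(1, len(factors) + 1), size)
    ]
    # degenerate-case tolerance, relative to the data's overall mean square
    ss_total = sum(ss.values())
    tol = 1e-12 * (ss_total / max(1, arr.size - 1))
    for subset in effect_subsets:
        err = subset | {0}
        name = " x ".join(factors[i - 1] for i in sorted(subset))
        ms_eff = ss[subset] / df[subset]
        ms_err = ss[err] / df[err]
        if ms_eff <= tol:
            f_stat = 0.0  # exactly null effect
        elif ms_err <= tol:
            f_stat = math.inf
        else:
            f_stat = ms_eff / ms_err
        df_num, df_den = df[subset], df[err]
        eps = 1.0
        if sphericity_correction and df_num > 1:
            # per-unit scores on this effect's margin cells
            axes = sorted(subset)
            collapse = tuple(
                i for i in range(1, len(factors) + 1) if i not in subset
            )
            cells = arr.mean(axis=collapse) if collapse else arr
            cells = cells.reshape(len(units), -1)
            eps = _gg_epsilon(cells)
        p = float(sps.f.sf(f_stat, df_num * eps, df_den * eps))
        rows.append(
            {
                "effect": name,
                "F": float(f_stat),
                "df_num": df_num,
                "df_den": df_den,
                "p": p,
                "eta_g_squared": ss[subset] / (ss[subset] + ss_unit_total),
                "ss_effect": ss[subset],
                "ss_error": ss[err],
                "gg_epsilon": eps,
            }
        )
    return pd.DataFrame(rows)


def holm_posthoc(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t-test: returns (t, df, p)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(arr, ddof=1) == 0:
        raise ValueError("zero variance: t undefined")
    res = sps.ttest_1samp(arr, mu0)
    return float(res.statistic), int(arr.size - 1), float(res.pvalue)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson correlation with two-sided t-based p; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


@dataclass
class SlopeResult:
    """Per-dyad pleasure-synchrony slopes and their group-level t-test."""

    slopes: pd.DataFrame  # dyad_id, slope, n_trials
    mean_slope: float
    sd_slope: float
    t: float
    df: int
    p: float
    convention: str
    skipped_dyads: tuple[str, ...] = ()


def pleasure_slope(
    trial_measures: pd.DataFrame,
    rating: str = "mean_rating",
    synchrony: str = "trial_log_mean_abs_diff",
    convention: str = "neg_log",
) -> SlopeResult:
    """Per-dyad OLS slope of synchrony score on mean pleasure rating.

    Under the default ``neg_log`` convention the synchrony score is the
    negated log mean absolute tap difference, so a positive slope means
    higher pleasure goes with tighter synchronization; ``log`` keeps the raw
    log difference (sign flipped). Dyads with fewer than 3 usable trials or
    zero rating variance are skipped with a warning entry and excluded from
    the group one-sample t-test against zero.
    """
    if convention not in ("neg_log", "log"):
        raise ValueError("convention must be 'neg_log' or 'log'")
    sign = -1.0 if convention == "neg_log" else 1.0
    rows = []
    skipped: list[str] = []
    data = trial_measures.dropna(subset=[rating, synchrony])
    for dyad, group in data.groupby("dyad_id"):
        r = group[rating].to_numpy(dtype=float)
        s = sign * group[synchrony].to_numpy(dtype=float)
        if len(group) < 3 or np.ptp(r) == 0:
            skipped.append(str(dyad))
            continue
        slope = float(np.polyfit(r, s, 1)[0])
        rows.append({"dyad_id": dyad, "slope": slope, "n_trials": len(group)})
    slopes = pd.DataFrame(rows)
    if len(slopes) < 2:
        raise ValueError("fewer than 2 dyads with estimable slopes")
    t, df, p = one_sample_t(slopes["slope"], 0.0)
    return SlopeResult(
        slopes=slopes,
        mean_slope=float(slopes["slope"].mean()),
        sd_slope=float(slopes["slope"].std(ddof=1)),
        t=t,
        df=df,
        p=p,
        convention=convention,
        skipped_dyads=tuple(skipped),
    )


def consonance_effect(
    trial_measures: pd.DataFrame,
    value: str = "trial_log_mean_abs_diff",
) -> pd.DataFrame:
    """Dyad-level consonance effect: mean consonant minus mean dissonant.

    Computed on each dyad's own trials (log mean absolute tap difference);
    negative values mean consonance tightened synchrony. Both consonance
    levels must be present for every dyad.
    """
    data = trial_measures.dropna(subset=[value])
    rows = []
    for dyad, group in data.groupby("dyad_id"):
        means = group.groupby("consonance")[value].mean()
        if "consonant" not in means or "dissonant" not in means:
            raise ValueError(f"dyad {dyad} is missing a consonance level")
        rows.append(
            {
                "dyad_id": dyad,
                "consonance_effect": float(means["consonant"] - means["dissonant"]),
                "mean_consonant": float(means["consonant"]),
                "mean_dissonant": float(means["dissonant"]),
            }
        )
    return pd.DataFrame(rows)
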