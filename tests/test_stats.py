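"""Repeated-measures ANOVA, Holm adjustment, slopes, consonance effects.

The RM-ANOVA is checked against two independent routes: a hand-worked
one-factor example, and statsmodels (OLS sums of squares on the saturated
factorial model, and AnovaRM F statistics) on randomly generated complete
grids.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.anova import AnovaRM

from dyadsync.stats import (
    aggregate_cells,
    consonance_effect,
    correlate,
    holm_posthoc,
    one_sample_t,
    pleasure_slope,
    rm_anova,
    ss_decomposition,
)


def random_grid(seed, n_units=4, factor_levels=(2, 3)):
    """Complete fully-within grid with N(0,1) cell values."""
    rng = np.random.default_rng(seed)
    factors = [f"f{i}" for i in range(len(factor_levels))]
    rows = []
    for u in range(n_units):
        for combo in itertools.product(*(range(l) for l in factor_levels)):
            rows.append(
                {
                    "unit": f"u{u}",
                    **{f: f"l{c}" for f, c in zip(factors, combo)},
                    "y": rng.normal(),
                }
            )
    return pd.DataFrame(rows), factors


def ols_sums_of_squares(grid, factors):
    """Brute-force SS decomposition via the saturated OLS factorial model."""
    terms = ["unit", *factors]
    formula = "y ~ " + "*".join(f"C({t})" for t in terms)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(smf.ols(formula, data=grid).fit(), typ=1)
    out = {}
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        parts = tuple(p[2:-1] for p in name.split(":"))  # strip C( )
        out[frozenset(terms.index(p) for p in parts)] = row["sum_sq"]
    return out


class TestSumsOfSquares:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize(
        "n_units,levels", [(2, (2,)), (3, (2, 2)), (4, (2, 3)), (3, (2, 2, 3))]
    )
    def test_equals_ols_decomposition(self, seed, n_units, levels):
        grid, factors = random_grid(1000 * seed + len(levels), n_units, levels)
        arr = (
            grid.set_index(["unit", *factors])["y"]
            .sort_index()
            .to_numpy()
            .reshape(n_units, *levels)
        )
        mine = ss_decomposition(arr)
        oracle = ols_sums_of_squares(grid, factors)
        assert set(mine) == set(oracle)
        for subset, ss in mine.items():
            assert ss == pytest.approx(oracle[subset], rel=1e-8, abs=1e-10)

    def test_total_ss_conserved(self):
        grid, factors = random_grid(7, 4, (2, 3))
        arr = grid["y"].to_numpy().reshape(4, 2, 3)
        ss = ss_decomposition(arr)
        assert sum(ss.values()) == pytest.approx(((arr - arr.mean()) ** 2).sum())


class TestRmAnova:
    def test_hand_worked_one_factor(self):
        # subjects (1,3) and (2,6): SS_A=9, SS_subj=4, SS_err=1
        grid = pd.DataFrame(
            {
                "unit": ["s1", "s1", "s2", "s2"],
                "a": ["l0", "l1", "l0", "l1"],
                "y": [1.0, 3.0, 2.0, 6.0],
            }
        )
        table = rm_anova(grid, "y", ["a"], "unit")
        row = table.iloc[0]
        assert row["F"] == pytest.approx(9.0)
        assert (row["df_num"], row["df_den"]) == (1, 1)
        assert row["ss_effect"] == pytest.approx(9.0)
        assert row["ss_error"] == pytest.approx(1.0)
        # one-factor ηG² reduces to SS_A / (SS_A + SS_subj + SS_err)
        assert row["eta_g_squared"] == pytest.approx(9.0 / 14.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_f_and_df_match_anova_rm(self, seed):
        grid, factors = random_grid(seed, n_units=5, factor_levels=(2, 3))
        mine = rm_anova(grid, "y", factors, "unit").set_index("effect")
        oracle = AnovaRM(grid, "y", "unit", within=factors).fit().anova_table
        for effect, row in oracle.iterrows():
            name = effect.replace(":", " x ")
            assert mine.loc[name, "F"] == pytest.approx(row["F Value"], rel=1e-6)
            assert mine.loc[name, "df_num"] == row["Num DF"]
            assert mine.loc[name, "df_den"] == row["Den DF"]
            assert mine.loc[name, "p"] == pytest.approx(row["Pr > F"], rel=1e-6)

    def test_constant_factor_gives_zero_f(self):
        grid, factors = random_grid(3, n_units=4, factor_levels=(2, 2))
        # make every unit's value identical across factor f0
        grid["y"] = grid.groupby(["unit", "f1"])["y"].transform("mean")
        table = rm_anova(grid, "y", factors, "unit").set_index("effect")
        assert table.loc["f0", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_eta_g_in_unit_interval(self):
        grid, factors = random_grid(11, n_units=4, factor_levels=(2, 3, 2))
        table = rm_anova(grid, "y", factors, "unit")
        assert ((table["eta_g_squared"] >= 0) & (table["eta_g_squared"] <= 1)).all()

    def test_incomplete_grid_rejected(self):
        grid, factors = random_grid(5, n_units=3, factor_levels=(2, 2))
        with pytest.raises(ValueError):
            rm_anova(grid.iloc[:-1], "y", factors, "unit")

    def test_single_unit_rejected(self):
        grid, factors = random_grid(5, n_units=1, factor_levels=(2, 2))
        with pytest.raises(ValueError, match="2 units"):
            rm_anova(grid, "y", factors, "unit")


class TestAggregateCells:
    def test_cell_count_and_identity_mean(self):
        rows = []
        for unit in ("d1", "d2"):
            for a in ("x", "y"):
                for rep in range(4):
                    rows.append({"unit": unit, "a": a, "v": 5.0})
        grid = aggregate_cells(pd.DataFrame(rows), "v", ["a"], "unit")
        assert len(grid) == 4  # 2 units x 2 cells
        assert (grid["v"] == 5.0).all()

    def test_missing_cell_is_error(self):
        frame = pd.DataFrame(
            {"unit": ["d1", "d1", "d2"], "a": ["x", "y", "x"], "v": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="empty cell"):
            aggregate_cells(frame, "v", ["a"], "unit")


class TestHolm:
    def test_hand_worked_step_down(self):
        adj = holm_posthoc([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_posthoc([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert holm_posthoc([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_posthoc([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_dominates_raw_and_is_monotone(self, ps):
        adj = holm_posthoc(ps)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        t, df, p = one_sample_t([6, 7, 8], mu0=7)
        assert t == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_direct_formula(self):
        t, df, p = one_sample_t([6, 7, 8], mu0=5)
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert t == pytest.approx(3.46, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([4, 4, 4], mu0=0)


class TestCorrelate:
    def test_perfect_linear(self):
        x = [0.0, 1.0, 2.0, 3.0]
        r, p, n = correlate(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_three_point_hand_formula(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 4.0])
        r, _, _ = correlate(x, y)
        expected = np.cov(x, y, ddof=0)[0, 1] / (x.std() * y.std())
        assert r == pytest.approx(expected, rel=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestPleasureSlope:
    def _frame(self):
        rows = []
        # dyad d1: log diff rises 1 per rating unit; d2: 0.5 per unit
        for i, (r, s) in enumerate([(2, 1.0), (3, 2.0), (4, 3.0)]):
            rows.append({"dyad_id": "d1", "trial_index": i, "mean_rating": r,
                         "trial_log_mean_abs_diff": s})
        for i, (r, s) in enumerate([(2, 1.0), (4, 2.0), (6, 3.0)]):
            rows.append({"dyad_id": "d2", "trial_index": i, "mean_rating": r,
                         "trial_log_mean_abs_diff": s})
        return pd.DataFrame(rows)

    def test_raw_log_convention_recovers_line(self):
        res = pleasure_slope(self._frame(), convention="log")
        slopes = res.slopes.set_index("dyad_id")["slope"]
        assert slopes["d1"] == pytest.approx(1.0)
        assert slopes["d2"] == pytest.approx(0.5)

    def test_neg_log_flips_sign(self):
        res = pleasure_slope(self._frame(), convention="neg_log")
        assert res.mean_slope == pytest.approx(-0.75)

    def test_zero_rating_variance_dyad_skipped(self):
        frame = self._frame()
        frame.loc[frame["dyad_id"] == "d1", "mean_rating"] = 5
        extra = frame[frame["dyad_id"] == "d2"].assign(dyad_id="d3")
        extra["trial_log_mean_abs_diff"] = [1.0, 2.5, 2.9]
        res = pleasure_slope(pd.concat([frame, extra]), convention="log")
        assert res.skipped_dyads == ("d1",)
        assert len(res.slopes) == 2


class TestConsonanceEffect:
    def _frame(self, shift=0.0):
        rows = []
        for i in range(4):
            rows.append({"dyad_id": "d1", "consonance": "consonant",
                         "trial_log_mean_abs_diff": 3.7 + shift})
            rows.append({"dyad_id": "d1", "consonance": "dissonant",
                         "trial_log_mean_abs_diff": 3.7})
        return pd.DataFrame(rows)

    def test_equal_means_give_zero(self):
        assert consonance_effect(self._frame())["consonance_effect"].iloc[0] == 0.0

    def test_uniform_shift(self):
        eff = consonance_effect(self._frame(shift=-0.1))
        assert eff["consonance_effect"].iloc[0] == pytest.approx(-0.1)

    def test_missing_level_rejected(self):
        frame = self._frame()
        with pytest.raises(ValueError, match="missing a consonance level"):
            consonance_effect(frame[frame["consonance"] == "consonant"])
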