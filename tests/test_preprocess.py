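"""Tap matching, exclusion rules and per-trial measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync.events import Phase, TrialCondition, TrialEvents
from dyadsync.preprocess import (
    OVER_THRESHOLD,
    POST_GONG,
    compute_itis,
    detect_glitch_trial,
    match_taps_to_metronome,
    moment_diagnostics,
    pair_dyad_taps,
    summarize_trial,
)
from dyadsync.simulate import AgentParams, EffectConfig, simulate_dyad_trial

CLICKS = [i * 500.0 for i in range(24)]
GONG = CLICKS[-1] + 20 * 500.0


def brute_force_nearest(ref, t):
    """Exhaustive nearest-neighbour with tie to the earlier event."""
    best = min(ref, key=lambda x: (abs(x - t), x))
    return best


class TestPairDyadTaps:
    def test_direct_arithmetic(self):
        pairs = pair_dyad_taps([0.0, 500.0, 1000.0], [10.0, 520.0, 990.0], 500, CLICKS, GONG)
        assert [p.abs_diff_ms for p in pairs] == [10.0, 20.0, 10.0]
        assert not any(p.excluded for p in pairs)

    def test_over_threshold_exclusion(self):
        pairs = pair_dyad_taps([0.0], [450.0], 500, CLICKS, GONG)
        assert pairs[0].excluded and pairs[0].reason == OVER_THRESHOLD

    def test_exact_threshold_kept(self):
        # the 80% rule is strict: abs diff of exactly 0.8*IOI is retained
        pairs = pair_dyad_taps([0.0], [400.0], 500, CLICKS, GONG)
        assert not pairs[0].excluded

    def test_post_gong_a_tap_not_emitted(self):
        pairs = pair_dyad_taps([100.0, GONG + 1], [90.0], 500, CLICKS, GONG)
        assert len(pairs) == 1

    def test_post_gong_b_member_flagged(self):
        pairs = pair_dyad_taps([GONG - 1], [GONG + 5], 500, CLICKS, GONG)
        assert pairs[0].excluded and pairs[0].reason == POST_GONG

    def test_empty_inputs(self):
        assert pair_dyad_taps([], [1.0], 500, CLICKS, GONG) == []
        assert pair_dyad_taps([1.0], [], 500, CLICKS, GONG) == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        taps_a=st.lists(st.integers(0, 2000), min_size=1, max_size=8, unique=True),
        taps_b=st.lists(st.integers(0, 2000), min_size=1, max_size=8, unique=True),
    )
    def test_matches_exhaustive_search(self, taps_a, taps_b):
        taps_a, taps_b = sorted(map(float, taps_a)), sorted(map(float, taps_b))
        pairs = pair_dyad_taps(taps_a, taps_b, 500, CLICKS, GONG)
        assert len(pairs) == len(taps_a)
        for ta, pair in zip(taps_a, pairs):
            assert pair.tap_b_ms == brute_force_nearest(taps_b, ta)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        taps_a=st.lists(st.integers(0, 2000), min_size=1, max_size=8, unique=True),
        taps_b=st.lists(st.integers(0, 2000), min_size=1, max_size=8, unique=True),
        shift=st.integers(-500, 500),
    )
    def test_shift_invariance(self, taps_a, taps_b, shift):
        taps_a, taps_b = sorted(map(float, taps_a)), sorted(map(float, taps_b))
        base = pair_dyad_taps(taps_a, taps_b, 500, CLICKS, math.inf)
        moved = pair_dyad_taps(
            [t + shift for t in taps_a],
            [t + shift for t in taps_b],
            500,
            [c + shift for c in CLICKS],
            math.inf,
        )
        assert [p.abs_diff_ms for p in base] == pytest.approx(
            [p.abs_diff_ms for p in moved]
        )


class TestMetronomeMatching:
    def test_signed_differences(self):
        matches = match_taps_to_metronome([495.0, 1003.0], [0.0, 500.0, 1000.0])
        assert [m.signed_diff_ms for m in matches] == [-5.0, 3.0]

    def test_tie_goes_to_earlier_click(self):
        matches = match_taps_to_metronome([250.0], [0.0, 500.0])
        assert matches[0].click_ms == 0.0

    def test_continuation_taps_ignored(self):
        clicks = [0.0, 500.0]
        matches = match_taps_to_metronome([400.0, 2000.0], clicks, 500.0, 5000.0)
        assert len(matches) == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        taps=st.lists(st.integers(0, 3000), min_size=1, max_size=8, unique=True),
        clicks=st.lists(st.integers(0, 3000), min_size=2, max_size=8, unique=True),
    )
    def test_matches_exhaustive_search(self, taps, clicks):
        clicks = sorted(map(float, clicks))
        ioi = clicks[1] - clicks[0]
        matches = match_taps_to_metronome(sorted(map(float, taps)), clicks, ioi)
        for m in matches:
            assert m.click_ms == brute_force_nearest(clicks, m.tap_ms)
            assert m.signed_diff_ms == m.tap_ms - m.click_ms


class TestItis:
    def test_first_differences(self):
        clicks = [0.0]  # everything after ioi/2 is continuation
        assert compute_itis([1000.0, 1540.0, 2090.0], clicks, 500.0) == [540.0, 550.0]

    def test_length_contract(self):
        clicks = [0.0]
        taps = [float(1000 + 500 * i) for i in range(21)]
        assert len(compute_itis(taps, clicks, 500.0)) == 20

    def test_fewer_than_two_taps(self):
        assert compute_itis([700.0], [0.0], 500.0) == []

    def test_noiseless_simulator_itis_equal_ioi(self):
        cond = TrialCondition("d", 1, 550.0, 200.0, 1)
        quiet = AgentParams(alpha=1.0, beta=0.0, sigma_tk=0.0, sigma_m=0.0)
        trial = simulate_dyad_trial(cond, quiet, quiet, EffectConfig(), rng_seed=0)
        itis = compute_itis(trial.taps_a, trial.clicks, 550.0, trial.gong_ms)
        assert itis == pytest.approx([550.0] * len(itis))


class TestGlitchDetection:
    def _trial(self, taps_a, taps_b):
        cond = TrialCondition("d", 1, 550.0, 200.0, 1)
        return TrialEvents(cond, cond.click_times(), taps_a, taps_b, cond.planned_gong_ms)

    def test_one_missing_participant(self):
        assert detect_glitch_trial(self._trial([], [100.0]))

    def test_both_present(self):
        assert not detect_glitch_trial(self._trial([100.0], [100.0]))

    def test_both_missing(self):
        assert detect_glitch_trial(self._trial([], []))


class TestSummarizeTrial:
    def _trial_with_taps(self, taps_a, taps_b, ratings=(6, 8)):
        cond = TrialCondition("d", 1, 550.0, 200.0, 5)
        return TrialEvents(
            cond, cond.click_times(), taps_a, taps_b, cond.planned_gong_ms,
            rating_a=ratings[0], rating_b=ratings[1],
        )

    def test_mean_and_log(self):
        trial = self._trial_with_taps(
            [2200.0, 2750.0, 3300.0], [2210.0, 2770.0, 3310.0]
        )
        m = summarize_trial(trial)
        sync = Phase.SYNCHRONIZATION
        assert m.mean_abs_diff_ms[sync] == pytest.approx(40.0 / 3.0)
        assert m.log_mean_abs_diff[sync] == pytest.approx(math.log(40.0 / 3.0), abs=1e-6)
        assert m.log_mean_abs_diff[sync] == pytest.approx(2.59, abs=0.005)
        assert m.mean_rating == 7.0

    def test_unit_mean_gives_log_zero(self):
        trial = self._trial_with_taps([2200.0, 2750.0], [2201.0, 2751.0])
        assert m_log(trial) == pytest.approx(0.0)

    def test_empty_phase_is_missing_not_zero(self):
        trial = self._trial_with_taps([2200.0], [2210.0])  # sync taps only
        m = summarize_trial(trial)
        assert Phase.CONTINUATION not in m.mean_abs_diff_ms
        assert Phase.CONTINUATION not in m.log_mean_abs_diff

    def test_exclusion_accounting(self, noisy_trial):
        m = summarize_trial(noisy_trial)
        n_a_pre_gong = sum(1 for t in noisy_trial.taps_a if t <= noisy_trial.gong_ms)
        total = sum(m.n_pairs_used.values()) + sum(m.n_pairs_excluded.values())
        assert total == n_a_pre_gong
        for phase in Phase:
            assert m.n_pairs_excluded[phase] == (
                m.n_excluded_post_gong[phase] + m.n_excluded_over_threshold[phase]
            )


def m_log(trial):
    return summarize_trial(trial).log_mean_abs_diff[Phase.SYNCHRONIZATION]


class TestMomentDiagnostics:
    def test_hand_computed_moments(self):
        skew, kurt = moment_diagnostics([-1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0)
        assert kurt == pytest.approx(1.5)

    def test_symmetric_data_zero_skew(self):
        skew, _ = moment_diagnostics([1, 2, 3, 4, 5, 6, 7])
        assert skew == pytest.approx(0.0)

    def test_normal_sample_kurtosis_near_three(self, rng):
        _, kurt = moment_diagnostics(rng.normal(size=200_000))
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            moment_diagnostics([2.0, 2.0, 2.0])
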