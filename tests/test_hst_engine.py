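"""Adaptive scale-search engine vs. the exhaustive minimum-audible-scale oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hearscreen import (
    NR,
    DomainError,
    EngineConfig,
    ScaleTable,
    ScreenClass,
    classify_scale,
    estimate_session_duration,
    is_nr,
    minimum_audible_scale_oracle,
    run_hst,
)
from hearscreen import test_retest as run_test_retest
from hearscreen.results import Presentation, ScreeningResult

FREQS = (1000, 2000, 4000, 500)


def det_responder(thresholds):
    """Idealized step listener: heard iff level >= threshold."""
    return lambda f, level: level >= thresholds[f]


def thresholds(v1000=0.0, v2000=0.0, v4000=0.0, v500=0.0):
    return {1000: v1000, 2000: v2000, 4000: v4000, 500: v500}


threshold_vectors = st.builds(
    thresholds,
    *[st.floats(min_value=-5, max_value=60, allow_nan=False) for _ in range(4)],
)


class TestOracle:
    @pytest.mark.parametrize(
        "thr, expected",
        [
            (thresholds(), 1),
            (thresholds(v1000=21.0), 6),
            (thresholds(v500=51.0), NR),
            (thresholds(18.0, 10.0, 5.0, 12.0), 5),
            (thresholds(v1000=32.0), 8),
        ],
    )
    def test_exhaustive_minimum_audible_scale(self, table, thr, expected):
        assert minimum_audible_scale_oracle(thr, table) == expected

    def test_missing_frequency_rejected(self, table):
        with pytest.raises(DomainError):
            minimum_audible_scale_oracle({1000: 0.0}, table)


class TestRunHst:
    @pytest.mark.parametrize(
        "thr, scale, cls",
        [
            (thresholds(0, 0, 0, 5.0), 1, ScreenClass.PASS),
            (thresholds(60.0, 60.0, 60.0, 60.0), NR, ScreenClass.FAIL),
            (thresholds(18.0, 10.0, 5.0, 12.0), 5, ScreenClass.PASS),
            (thresholds(v1000=32.0), 8, ScreenClass.FAIL),
        ],
    )
    def test_known_threshold_profiles(self, table, rng, thr, scale, cls):
        res = run_hst(det_responder(thr), table, rng=rng)
        assert res.assigned_scale == scale
        assert res.classification is cls

    @given(thr=threshold_vectors)
    @settings(derandomize=True, max_examples=300)
    def test_engine_agrees_with_oracle(self, thr):
        table = ScaleTable()
        res = run_hst(det_responder(thr), table, rng=np.random.default_rng(0))
        assert res.assigned_scale == minimum_audible_scale_oracle(thr, table)

    @given(thr=threshold_vectors, bump=st.floats(min_value=0, max_value=30),
           which=st.sampled_from(FREQS))
    @settings(derandomize=True, max_examples=200)
    def test_raising_a_threshold_never_lowers_the_scale(self, thr, bump, which):
        table = ScaleTable()

        def rank(t):
            s = minimum_audible_scale_oracle(t, table)
            return table.max_scale + 1 if is_nr(s) else s

        raised = dict(thr)
        raised[which] = raised[which] + bump
        assert rank(raised) >= rank(thr)

    @given(thr=threshold_vectors)
    @settings(derandomize=True, max_examples=200)
    def test_logged_scales_step_by_one_and_are_monotone(self, thr):
        res = run_hst(det_responder(thr), rng=np.random.default_rng(0))
        visited = res.scales_visited()
        assert visited[0] == 5  # always starts at the mid-ladder scale
        steps = [b - a for a, b in zip(visited, visited[1:])]
        assert all(s in (-1, 1) for s in steps)
        # unimodal: pure descent or pure ascent from the start scale
        assert len(set(steps)) <= 1

    @given(thr=threshold_vectors)
    @settings(derandomize=True, max_examples=200)
    def test_classification_and_levels_consistent_with_table(self, thr):
        table = ScaleTable()
        res = run_hst(det_responder(thr), table, rng=np.random.default_rng(0))
        assert res.classification is classify_scale(res.assigned_scale)
        for p in res.presentations:
            assert p.level_db_hl == table.level(p.frequency_hz, p.scale)

    def test_tone_order_fixed_within_each_scale(self, rng):
        res = run_hst(
            det_responder(thresholds()),
            config=EngineConfig(abort_scale_on_first_miss=False),
            rng=rng,
        )
        for s in res.scales_visited():
            freqs = tuple(p.frequency_hz for p in res.presentations if p.scale == s)
            assert freqs == FREQS

    def test_strict_mode_presents_all_four_tones_per_scale(self, rng):
        thr = thresholds(v1000=60.0, v2000=60.0, v4000=60.0, v500=60.0)
        res = run_hst(
            det_responder(thr),
            config=EngineConfig(abort_scale_on_first_miss=False),
            rng=rng,
        )
        assert len(res.presentations) == 4 * 6  # S_5 then ascent S_6..S_10

    def test_bad_start_scale_rejected(self, table, rng):
        from hearscreen import ConfigError

        with pytest.raises(ConfigError):
            run_hst(det_responder(thresholds()), table,
                    EngineConfig(start_scale=11), rng)


class TestRetest:
    def test_deterministic_listener_agrees_exactly(self, rng):
        thr = thresholds(18.0, 10.0, 5.0, 12.0)
        r1, r2, agreement = run_test_retest(det_responder(thr), rng=rng)
        assert r1.assigned_scale == r2.assigned_scale == 5
        assert agreement.exact_match and agreement.scale_difference == 0

    def test_double_nr_counts_as_agreement(self, rng):
        thr = thresholds(90.0, 90.0, 90.0, 90.0)
        _, _, agreement = run_test_retest(det_responder(thr), rng=rng)
        assert is_nr(agreement.first) and is_nr(agreement.second)
        assert agreement.exact_match and agreement.scale_difference == 0

    def test_steep_slope_listeners_repeat_within_one_scale(self):
        # near-deterministic listeners should give stable scale assignments
        from hearscreen import SimulatedListener

        root = np.random.SeedSequence(2024)
        n, within_one = 500, 0
        for child in root.spawn(n):
            r = np.random.default_rng(child)
            thr = float(r.uniform(0, 40))
            listener = SimulatedListener(
                thresholds_db_hl={f: thr for f in FREQS}, slope_db=0.5
            )
            _, _, agreement = run_test_retest(listener.responder(r), rng=r)
            if abs(agreement.scale_difference) <= 1:
                within_one += 1
        assert within_one / n >= 0.95


class TestSessionDuration:
    def test_sum_of_tone_and_realized_isi(self):
        pres = tuple(
            Presentation(1000, 20.0, 5, True, onset_s=i * 4.0, isi_s=2.5)
            for i in range(4)
        )
        res = ScreeningResult(5, ScreenClass.PASS, pres)
        assert estimate_session_duration(res, tone_duration_s=1.5) == pytest.approx(16.0)

    def test_empty_log_is_zero(self):
        res = ScreeningResult(5, ScreenClass.PASS, ())
        assert estimate_session_duration(res) == 0.0

    def test_worst_case_run_fits_in_three_minutes(self, rng):
        # NR outcome without early abort: 6 scales x 4 tones, ISI <= 3 s
        thr = thresholds(90.0, 90.0, 90.0, 90.0)
        res = run_hst(
            det_responder(thr),
            config=EngineConfig(abort_scale_on_first_miss=False),
            rng=rng,
        )
        assert estimate_session_duration(res) <= 180.0
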