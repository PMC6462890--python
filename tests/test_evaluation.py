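"""Contingency tables, diagnostic metrics, group summaries, and protocol comparison."""

import itertools
import math

import numpy as np
import pytest

from hearscreen import (
    NR,
    ContingencyTable,
    DomainError,
    ScreenClass,
    ScreeningResult,
    SimulatedListener,
    compare_protocols,
    contingency,
    protocol_preset,
    run_protocol_on_cohort,
    scale_group_summary,
    scale_pta_correlation,
    screen_metrics,
)

PASS, FAIL = ScreenClass.PASS, ScreenClass.FAIL
FREQS = (500, 1000, 2000, 4000)


def result(scale):
    cls = FAIL if scale is NR or scale > 5 else PASS
    return ScreeningResult(scale, cls)


class TestContingency:
    def test_study_cohort_yields_two_true_positives(self, study_cohort, study_hst_results):
        table = contingency(
            [r.classification for r in study_hst_results],
            [l.impaired for l in study_cohort],
        )
        assert (table.tp, table.fp, table.fn, table.tn) == (2, 0, 0, 168)

    def test_all_pass_all_normal(self):
        table = contingency([PASS] * 7, [False] * 7)
        assert (table.tp, table.fp, table.fn, table.tn) == (0, 0, 0, 7)

    def test_cell_placement_exhaustively_on_three_ears(self):
        # brute force over every pass/fail x impaired/normal assignment
        for screens in itertools.product([PASS, FAIL], repeat=3):
            for refs in itertools.product([False, True], repeat=3):
                table = contingency(list(screens), list(refs))
                expect_tp = sum(s is FAIL and r for s, r in zip(screens, refs))
                expect_fp = sum(s is FAIL and not r for s, r in zip(screens, refs))
                expect_fn = sum(s is PASS and r for s, r in zip(screens, refs))
                expect_tn = sum(s is PASS and not r for s, r in zip(screens, refs))
                assert (table.tp, table.fp, table.fn, table.tn) == (
                    expect_tp, expect_fp, expect_fn, expect_tn,
                )
                assert table.total == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            contingency([PASS], [True, False])


class TestScreenMetrics:
    def test_perfect_screen(self):
        m = screen_metrics(ContingencyTable(2, 0, 0, 168))
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.ppv == 1.0 and m.npv == 1.0
        assert m.false_positive_rate == 0.0 and m.false_negative_rate == 0.0

    def test_one_missed_impaired_ear(self):
        m = screen_metrics(ContingencyTable(20, 0, 1, 149))
        assert m.sensitivity == pytest.approx(20 / 21)
        assert m.false_negative_rate == pytest.approx(1 / 21)

    def test_zero_denominator_yields_nan_not_zero(self):
        m = screen_metrics(ContingencyTable(0, 0, 0, 170))
        assert math.isnan(m.sensitivity) and math.isnan(m.false_negative_rate)
        assert math.isnan(m.ppv)
        assert m.specificity == 1.0 and m.npv == 1.0

    def test_transposed_table_swaps_sensitivity_and_specificity(self):
        table = ContingencyTable(5, 3, 2, 40)
        m, mt = screen_metrics(table), screen_metrics(table.transposed())
        assert mt.sensitivity == pytest.approx(m.specificity)
        assert mt.specificity == pytest.approx(m.sensitivity)


class TestScaleGroupSummary:
    def test_study_cohort_reproduces_the_published_rows(
        self, study_cohort, study_hst_results
    ):
        summary, n_nr = scale_group_summary(
            study_hst_results, [l.booth_pta_db for l in study_cohort]
        )
        assert n_nr == 0
        assert summary["scale"].tolist() == [1, 2, 3, 4, 5, 7, 8]
        assert summary["n"].tolist() == [16, 58, 59, 27, 8, 1, 1]
        assert summary["n"].sum() == 170
        assert summary["mean_pta_db"].tolist() == [5.0, 7.0, 9.0, 11.0, 12.0, 31.0, 36.0]

    def test_single_ear_group_has_undefined_sd(self):
        summary, _ = scale_group_summary([result(7)], [31.0])
        assert summary["n"].tolist() == [1]
        assert math.isnan(summary["sd_pta_db"].iloc[0])

    def test_nr_ears_reported_separately(self):
        summary, n_nr = scale_group_summary([result(3), result(NR)], [9.0, 55.0])
        assert n_nr == 1
        assert summary["n"].sum() == 1

    def test_empty_input(self):
        summary, n_nr = scale_group_summary([], [])
        assert summary.empty and n_nr == 0


class TestCorrelation:
    def test_perfectly_linear_relation(self):
        results = [result(s) for s in (1, 2, 3, 4, 5)]
        ptas = [5 * s for s in (1, 2, 3, 4, 5)]
        assert scale_pta_correlation(results, ptas) == pytest.approx(1.0)

    def test_zero_variance_is_undefined(self):
        results = [result(3)] * 5
        assert math.isnan(scale_pta_correlation(results, [5, 7, 9, 11, 12]))

    def test_matches_textbook_formula_on_the_study_cohort(
        self, study_cohort, study_hst_results
    ):
        ptas = [l.booth_pta_db for l in study_cohort]
        got = scale_pta_correlation(study_hst_results, ptas)
        # independent recomputation from the definition
        xs = np.array([r.assigned_scale for r in study_hst_results], dtype=float)
        ys = np.array(ptas, dtype=float)
        num = np.sum((xs - xs.mean()) * (ys - ys.mean()))
        den = math.sqrt(np.sum((xs - xs.mean()) ** 2) * np.sum((ys - ys.mean()) ** 2))
        assert got == pytest.approx(num / den, rel=1e-12)
        assert got > 0.5  # scales track the booth thresholds

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            scale_pta_correlation([result(1), result(2)], [5.0, 7.0])


class TestCompareProtocols:
    def test_adaptive_protocol_is_perfect_on_the_study_cohort(self, study_cohort):
        frame = compare_protocols(study_cohort, [protocol_preset("HST")], seed=0)
        row = frame.loc["HST"]
        assert row.sensitivity == 1.0 and row.specificity == 1.0
        assert row.false_negative_rate == 0.0 and row.false_positive_rate == 0.0

    def test_false_positive_rate_complements_specificity(self, study_cohort):
        frame = compare_protocols(
            study_cohort,
            [protocol_preset(n) for n in ("HST", "AAP", "ASHA_as_tested")],
            seed=0,
        )
        for _, row in frame.iterrows():
            assert row.false_positive_rate == pytest.approx(1.0 - row.specificity)

    def test_stricter_level_detects_an_ear_the_laxer_level_misses(self):
        # impaired ear whose app-domain thresholds sit between 15 and 20 dB:
        # the 15 dB screen fails it (detected), the 20 dB screen passes it
        borderline = SimulatedListener(
            thresholds_db_hl={f: 18.0 for f in FREQS}, booth_pta_db=30.0
        )
        normal = SimulatedListener(
            thresholds_db_hl={f: 0.0 for f in FREQS}, booth_pta_db=5.0
        )
        cohort = [borderline, normal]
        frame = compare_protocols(
            cohort,
            [protocol_preset("ASHA_as_tested"), protocol_preset("AAP")],
            seed=0,
        )
        assert frame.loc["ASHA_as_tested"].sensitivity == 1.0
        assert frame.loc["AAP"].sensitivity == 0.0
        assert frame.loc["AAP"].specificity == 1.0

    def test_deterministic_cohort_gives_identical_tables_across_runs(self, study_cohort):
        protos = [protocol_preset("HST"), protocol_preset("AAP")]
        a = compare_protocols(study_cohort, protos, seed=3)
        b = compare_protocols(study_cohort, protos, seed=3)
        assert a.equals(b)

    def test_missing_cohort_frequency_rejected(self):
        from hearscreen import ConfigError

        lopsided = SimulatedListener(thresholds_db_hl={1000: 0.0}, booth_pta_db=5.0)
        with pytest.raises(ConfigError):
            run_protocol_on_cohort([lopsided], protocol_preset("AAP"))
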