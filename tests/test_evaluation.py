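"""Accuracy accounting, Wald intervals, QoL scoring, cohort statistics."""
import math

import numpy as np
import pytest

from epicollar import (
    QoLResponse,
    change_correlation,
    evaluate_phase,
    exclude_nonwear_seizures,
    false_detection_rate,
    match_events,
    paired_change_stats,
    qol_composite,
    sensitivity_ci,
)
from epicollar.evaluation import REVERSE_CODED_DEFAULT, pooled_sensitivity
from epicollar.simulate import SeizureEvent

from conftest import at, iv


def ev(t0, t1):
    return SeizureEvent(at(t0), at(t1))


class TestExcludeNonwear:
    def test_no_gaps_all_kept(self):
        kept, excl = exclude_nonwear_seizures([ev(0, 60), ev(100, 160)], [])
        assert len(kept) == 2 and excl == []

    def test_fully_inside_gap_excluded(self):
        kept, excl = exclude_nonwear_seizures([ev(10, 40)], [iv(0, 100)])
        assert kept == [] and len(excl) == 1

    def test_straddling_gap_edge_excluded(self):
        # any positive-duration intersection excludes
        kept, excl = exclude_nonwear_seizures([ev(90, 150)], [iv(0, 100)])
        assert kept == [] and len(excl) == 1

    def test_touching_gap_boundary_kept(self):
        # half-open: seizure starting exactly at gap end does not intersect
        kept, excl = exclude_nonwear_seizures([ev(100, 160)], [iv(0, 100)])
        assert len(kept) == 1 and excl == []


class TestMatchEvents:
    def test_exact_overlap_pair(self):
        m = match_events([ev(10, 40)], [ev(10, 40)], 60.0)
        assert (m.n_tp, m.n_fn, m.n_fp) == (1, 0, 0)

    def test_two_detections_one_seizure_single_tp(self):
        m = match_events([ev(12, 16), ev(30, 34)], [ev(10, 40)], 60.0)
        assert (m.n_tp, m.n_fn, m.n_fp) == (1, 0, 0)

    def test_distant_detection_is_fp(self):
        m = match_events([ev(600, 640)], [ev(10, 40)], 60.0)
        assert (m.n_tp, m.n_fn, m.n_fp) == (0, 1, 1)

    def test_tolerance_window(self):
        m = match_events([ev(95, 100)], [ev(10, 40)], 60.0)
        assert m.n_tp == 1  # 55 s gap, within tolerance
        m = match_events([ev(101, 105)], [ev(10, 40)], 60.0)
        assert (m.n_tp, m.n_fp) == (0, 1)

    def test_randomized_against_enumeration(self, rng):
        """Counts match a direct enumeration of the matching rule."""
        from epicollar.intervals import within_tolerance

        for _ in range(300):
            truth = sorted(rng.uniform(0, 2000, size=rng.integers(0, 6)))
            dets = sorted(rng.uniform(0, 2000, size=rng.integers(0, 8)))
            tev = [ev(t, t + 30) for t in truth]
            dev_ = [ev(d, d + 10) for d in dets]
            m = match_events(dev_, tev, 60.0)
            tp = sum(
                any(within_tolerance((t.start, t.end), (d.start, d.end), 60.0)
                    for d in dev_)
                for t in tev
            )
            fp = sum(
                not any(within_tolerance((t.start, t.end), (d.start, d.end), 60.0)
                        for t in tev)
                for d in dev_
            )
            assert (m.n_tp, m.n_fn, m.n_fp) == (tp, len(tev) - tp, fp)


class TestSensitivityCI:
    def test_phase1_field_counts(self):
        assert sensitivity_ci(40, 215) == (18.6, 13.4, 23.8)

    def test_phase2_field_counts(self):
        assert sensitivity_ci(30, 136) == (22.1, 15.1, 29.0)

    def test_hand_computed_small_case(self):
        # p = .5, half-width = 1.96 sqrt(.25/10) = .30990
        assert sensitivity_ci(5, 10) == (50.0, 19.0, 81.0)

    def test_degenerate_zero_detections(self):
        assert sensitivity_ci(0, 50) == (0.0, 0.0, 0.0)

    def test_no_evaluable_seizures_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_ci(0, 0)

    def test_interval_contains_point_and_shrinks(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            p, lo, hi = sensitivity_ci(k, n)
            assert lo <= p <= hi
        widths = [sensitivity_ci(n // 5, n)[2] - sensitivity_ci(n // 5, n)[1]
                  for n in (50, 500, 5000, 50000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_wilson_option_sane(self):
        p, lo, hi = sensitivity_ci(5, 10, method="wilson")
        assert p == 50.0 and 0 < lo < 50 < hi < 100


class TestFalseDetectionRate:
    def test_zero_fps(self):
        rate, days = false_detection_rate(0, 93.0, [])
        assert rate == 0.0 and days == 93.0

    def test_hand_worked_gap_correction(self):
        # gaps of 26 h, 30 h, 49 h -> 1 + 1 + 2 whole days subtracted
        mask = [iv(0, 26 * 3600), iv(30 * 3600, 60 * 3600),
                iv(100 * 3600, 149 * 3600)]
        rate, days = false_detection_rate(9, 93.0, mask)
        assert days == 89.0
        assert rate == pytest.approx(9 / 89)

    def test_short_gap_no_subtraction(self):
        rate, days = false_detection_rate(2, 10.0, [iv(0, 23 * 3600)])
        assert days == 10.0

    def test_total_rule_option(self):
        _, days = false_detection_rate(0, 10.0, [iv(0, 36 * 3600)], rule="total")
        assert days == pytest.approx(10.0 - 1.5)

    def test_adding_gap_never_increases_days(self, rng):
        days0 = 30.0
        masks = [[], [iv(0, 20 * 3600)], [iv(0, 20 * 3600), iv(30 * 3600, 80 * 3600)]]
        days = [false_detection_rate(0, days0, m)[1] for m in masks]
        assert days[0] >= days[1] >= days[2]

    def test_uninterpretable_phase_rejected(self):
        with pytest.raises(ValueError):
            false_detection_rate(1, 1.0, [iv(0, 48 * 3600)])


class TestQoL:
    def test_most_favorable_is_75(self):
        items = tuple(1 if i in REVERSE_CODED_DEFAULT else 5 for i in range(15))
        assert qol_composite(QoLResponse(items)) == 75

    def test_least_favorable_is_15(self):
        items = tuple(5 if i in REVERSE_CODED_DEFAULT else 1 for i in range(15))
        assert qol_composite(QoLResponse(items)) == 15

    def test_all_threes_midpoint(self):
        assert qol_composite(QoLResponse((3,) * 15)) == 45

    def test_hand_scored_sheet(self):
        items = [2, 4, 3, 5, 1, 2, 5, 3, 4, 2, 1, 5, 4, 3, 2]
        # standardize: reverse items {1,4,6,9,12} -> 6-v
        expected = sum(
            6 - v if i in REVERSE_CODED_DEFAULT else v for i, v in enumerate(items)
        )
        assert qol_composite(QoLResponse(tuple(items))) == expected == 44

    def test_reverse_coding_involution(self, rng):
        for _ in range(50):
            items = tuple(int(v) for v in rng.integers(1, 6, size=15))
            r = QoLResponse(items)
            double = QoLResponse(r.standardized(), frozenset())
            flipped_back = tuple(
                6 - v if i in REVERSE_CODED_DEFAULT else v
                for i, v in enumerate(r.standardized())
            )
            assert flipped_back == items
            assert qol_composite(double) == qol_composite(r)

    @pytest.mark.parametrize("items", [(0,) + (3,) * 14, (6,) + (3,) * 14, (3,) * 14])
    def test_invalid_sheets_rejected(self, items):
        with pytest.raises(ValueError):
            QoLResponse(tuple(items))


class TestPairedStats:
    def test_identical_vectors(self):
        s = paired_change_stats([40, 45, 50], [40, 45, 50])
        assert s.t_stat == 0.0 and s.p_value == 1.0

    def test_hand_worked_five_pairs(self):
        initial = [40, 42, 38, 45, 41]
        final = [50, 49, 44, 50, 47]
        s = paired_change_stats(initial, final)
        d = np.array(final) - np.array(initial)
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(5))
        assert s.t_stat == pytest.approx(t_hand)
        assert s.mean_initial == pytest.approx(41.2)
        assert s.mean_final == pytest.approx(48.0)
        assert 0 < s.p_value < 0.01

    def test_constant_shift_degenerate_flagged(self):
        s = paired_change_stats([10, 20, 30], [20, 30, 40])
        assert s.degenerate and s.t_stat == math.inf

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_change_stats([1, 2], [1, 2, 3])


class TestChangeCorrelation:
    def test_perfectly_linear(self):
        r, _ = change_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_anti_linear(self):
        r, _ = change_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_worked_four_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        r, p = change_correlation(x, y)
        assert r == pytest.approx(r_hand)
        assert 0 <= p <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            change_correlation([1, 1, 1], [1, 2, 3])


class TestEvaluatePhaseAndPooling:
    def test_excluding_seizure_never_changes_fp(self):
        truth = [ev(10, 40), ev(5000, 5060)]
        dets = [ev(12, 30), ev(9000, 9040)]
        r_nogap = evaluate_phase("d", 1, truth, dets, [], 1.0)
        r_gap = evaluate_phase("d", 1, truth, dets, [iv(4990, 5100)], 1.0)
        assert r_gap.n_excluded_nonwear == 1
        assert r_gap.n_fp == r_nogap.n_fp == 1

    def test_report_count_identity(self):
        truth = [ev(10, 40), ev(500, 560), ev(900, 950)]
        dets = [ev(12, 30)]
        r = evaluate_phase("d", 1, truth, dets, [iv(880, 1000)], 2.0)
        assert r.n_tp + r.n_fn == r.n_seizures_total - r.n_excluded_nonwear
        assert r.n_tp == 1 and r.n_fn == 1 and r.n_excluded_nonwear == 1

    def test_pooled_differs_from_mean_per_dog(self):
        """Pooled = sum TP / sum evaluable; with heterogeneous per-dog
        counts this differs from the mean of per-dog sensitivities."""
        r1 = evaluate_phase("a", 1, [ev(0, 30)], [ev(0, 30)], [], 1.0)  # 1/1
        truth_b = [ev(i * 500, i * 500 + 30) for i in range(9)]
        r2 = evaluate_phase("b", 1, truth_b, [ev(0, 30)], [], 1.0)  # 1/9
        pooled = pooled_sensitivity([r1, r2])
        assert pooled["pooled"][0] == pytest.approx(round(100 * 2 / 10, 1))
        mean = pooled["mean_per_dog_sensitivity"]
        assert mean == pytest.approx((100.0 + round(100 / 9, 1)) / 2)
        assert abs(mean - pooled["pooled"][0]) > 10

    def test_dogs_without_evaluable_seizures_skip_mean(self):
        r1 = evaluate_phase("a", 1, [], [], [], 1.0)
        r2 = evaluate_phase("b", 1, [ev(0, 30)], [ev(0, 30)], [], 1.0)
        pooled = pooled_sensitivity([r1, r2])
        assert r1.sensitivity is None
        assert pooled["mean_per_dog_sensitivity"] == 100.0
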