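"""Detection rules, evaluation indices and the Weighted Discriminator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurogait import (
    DetectionRecord,
    EvaluationReport,
    ValidationError,
    aggregate_reports,
    compute_indices,
    detect_events,
    round_half_away,
    score_epochs,
    weighted_discriminator,
)

OFFLINE_FP_MIN = 4.0 / 60.0
PSEUDO_FP_MIN = 1.0 / 60.0


def record(active, nonactive, minutes=1.0, protocol="pseudo_online"):
    return DetectionRecord(
        active_outcomes=[np.array(a, bool) for a in active],
        nonactive_outcomes=[np.array(n, bool) for n in nonactive],
        nonactive_minutes=minutes,
        protocol=protocol,
    )


class TestScoreEpochs:
    def test_identical_all_true(self):
        assert np.all(score_epochs([1, 0, 1], [1, 0, 1]))

    def test_complementary_all_false(self):
        assert not np.any(score_epochs([1, 0, 1], [0, 1, 0]))

    def test_elementwise_mix(self):
        np.testing.assert_array_equal(score_epochs([1, 0, 1], [1, 1, 1]), [True, False, True])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            score_epochs([1, 0], [1])


def brute_force_runs(seq, k=5):
    """Enumerate maximal runs by inspection: (has T-run >= k, count of F-runs >= k)."""
    has_t = False
    f_runs = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] and (j - i) >= k:
            has_t = True
        if not seq[i] and (j - i) >= k:
            f_runs += 1
        i = j
    return has_t, f_runs


class TestDetectEvents:
    def test_offline_majority_rule(self):
        r = detect_events(record([[True] * 9 + [False] * 7], [], protocol="offline"))
        assert r.detected == [True]
        r = detect_events(record([[True] * 8 + [False] * 8], [], protocol="offline"))
        assert r.detected == [False]  # a tie is not a detection

    def test_offline_nonactive_one_fp_max(self):
        r = detect_events(record([[True]], [[False] * 12 + [True] * 4], protocol="offline"))
        assert r.false_activations == 1

    def test_pseudo_online_needs_five_consecutive(self):
        seq = [True] * 4 + [False] + [True] * 4
        r = detect_events(record([seq], []))
        assert r.detected == [False]
        r = detect_events(record([[False] * 3 + [True] * 5 + [False] * 3], []))
        assert r.detected == [True]

    def test_pseudo_online_long_false_run_counts_once(self):
        r = detect_events(record([[True] * 5], [[False] * 12]))
        assert r.false_activations == 1

    def test_floor_div_counting_alternative(self):
        r = detect_events(record([[True] * 5], [[False] * 12]), fp_counting="floor_div")
        assert r.false_activations == 2

    def test_exhaustive_enumeration_oracle(self):
        for n in range(13):
            for bits in itertools.product([True, False], repeat=n):
                seq = list(bits)
                r = detect_events(record([seq], [seq]))
                has_t, f_runs = brute_force_runs(seq)
                assert r.detected == [has_t], seq
                assert r.false_activations == f_runs, seq


class TestComputeIndices:
    def test_one_of_four_detected_nothing_false(self):
        # the canonical cautionary case: perfect-looking Acc and FP/min but TPR 25%
        active = [[True] * 5, [False] * 5, [False] * 5, [False] * 5]
        r = detect_events(record(active, [[True] * 20], minutes=1.0))
        rep = compute_indices(r)
        assert rep.tpr_pct == pytest.approx(25.0)
        assert rep.acc_pct == pytest.approx(100.0)
        assert rep.fp_per_min == 0.0

    def test_all_detected(self):
        active = [[True] * 5] * 4
        rep = compute_indices(detect_events(record(active, [], minutes=0.5)))
        assert rep.tpr_pct == 100.0 and rep.acc_pct == 100.0

    def test_mixed_detections_and_fps(self):
        active = [[True] * 5] * 4
        nonactive = [[False] * 5 + [True] + [False] * 5]
        rep = compute_indices(detect_events(record(active, nonactive, minutes=0.5)))
        assert rep.acc_pct == pytest.approx(4 / 6 * 100, rel=1e-9)
        assert rep.fp_per_min == pytest.approx(4.0)

    def test_undefined_acc_flagged(self):
        rep = compute_indices(detect_events(record([[False] * 5], [[True] * 5], minutes=1.0)))
        assert rep.acc_pct is None and rep.wd is None

    def test_zero_nonactive_time_rejected(self):
        with pytest.raises(ValidationError, match="FP/min"):
            compute_indices(detect_events(record([[True] * 5], [], minutes=0.0)))


class TestWeightedDiscriminator:
    @pytest.mark.parametrize(
        "tpr,acc,fpmin,dur,expected",
        [
            (100.0, 100.0, 0.0, PSEUDO_FP_MIN, 1.00),
            (87.50, 98.00, 0.38, OFFLINE_FP_MIN, 0.91),
            (62.50, 100.00, 0.00, PSEUDO_FP_MIN, 0.85),
            (100.00, 83.57, 5.14, PSEUDO_FP_MIN, 0.82),
            (0.0, 0.0, 60.0, PSEUDO_FP_MIN, -1.00),
        ],
    )
    def test_published_style_worked_examples(self, tpr, acc, fpmin, dur, expected):
        assert weighted_discriminator(tpr, acc, fpmin, dur) == pytest.approx(expected)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.915) == 0.92
        assert round_half_away(-0.915) == -0.92
        assert round_half_away(0.914999) == 0.91

    def test_perfect_iff_all_perfect(self):
        assert weighted_discriminator(100, 100, 0, OFFLINE_FP_MIN, round_to=None) == 1.0
        assert weighted_discriminator(100, 100, 0.1, OFFLINE_FP_MIN, round_to=None) < 1.0
        assert weighted_discriminator(99.9, 100, 0, OFFLINE_FP_MIN, round_to=None) < 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0, 15),
    )
    def test_monotonicity(self, tpr, acc, fpmin):
        base = weighted_discriminator(tpr, acc, fpmin, PSEUDO_FP_MIN, round_to=None)
        if tpr <= 99:
            assert weighted_discriminator(tpr + 1, acc, fpmin, PSEUDO_FP_MIN, round_to=None) > base
        if acc <= 99:
            assert weighted_discriminator(tpr, acc + 1, fpmin, PSEUDO_FP_MIN, round_to=None) > base
        assert weighted_discriminator(tpr, acc, fpmin + 1, PSEUDO_FP_MIN, round_to=None) < base

    def test_bounded_when_fpr_bounded(self):
        # WD stays in [-1, 1] while FPR <= 1 + 0.4 TPR + 0.6 Acc (per-unit)
        rng = np.random.default_rng(0)
        for _ in range(200):
            tpr, acc = rng.uniform(0, 100, 2)
            fpr_max = 1 + 0.4 * tpr / 100 + 0.6 * acc / 100
            fpmin = rng.uniform(0, fpr_max) / PSEUDO_FP_MIN
            wd = weighted_discriminator(tpr, acc, fpmin, PSEUDO_FP_MIN, round_to=None)
            assert -1.0 - 1e-12 <= wd <= 1.0 + 1e-12


class TestAggregateReports:
    def rep(self, tpr, acc, fp, protocol="offline"):
        return EvaluationReport(
            tpr_pct=tpr,
            acc_pct=acc,
            fp_per_min=fp,
            fp_duration_min=OFFLINE_FP_MIN if protocol == "offline" else PSEUDO_FP_MIN,
            protocol=protocol,
            n_events=4,
        )

    def test_single_report_is_its_own_mean(self):
        s = aggregate_reports([self.rep(50.0, 80.0, 1.0)])
        assert s.mean.tpr_pct == 50.0 and s.sd["tpr_pct"] == 0.0

    def test_mean_of_two_wds(self):
        s = aggregate_reports([self.rep(100, 100, 9.0), self.rep(100, 100, 6.0)])
        assert s.mean.wd == pytest.approx(0.5)

    def test_wd_linearity_under_averaging(self):
        reports = [self.rep(80, 90, 2.0), self.rep(60, 70, 1.0), self.rep(100, 85, 0.5)]
        s = aggregate_reports(reports)
        mean_of_wds = np.mean([r.wd for r in reports])
        assert s.mean.wd == pytest.approx(mean_of_wds, rel=1e-12)

    def test_undefined_acc_excluded_and_counted(self):
        r_undef = EvaluationReport(0.0, None, 0.0, OFFLINE_FP_MIN, "offline")
        s = aggregate_reports([self.rep(100, 90, 0.0), r_undef])
        assert s.n_acc_undefined == 1
        assert s.mean.acc_pct == pytest.approx(90.0)

    def test_mixed_protocols_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_reports([self.rep(1, 1, 1), self.rep(1, 1, 1, protocol="pseudo_online")])
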