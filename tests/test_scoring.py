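"""Zone/direction investigation rule, trial alignment, manual import."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from ohdkit.paradigm import TrialWindow
from ohdkit.scoring import (
    AWAY,
    STATIONARY,
    TOWARD,
    InvestigationBout,
    ScoringError,
    ZoneRule,
    cm_to_px,
    detect_bouts,
    distance_from_primary,
    frames_to_seconds,
    import_manual_bouts,
    investigating_frames,
    motion_labels,
    score_trials,
)
from ohdkit.telemetry import TrackingCalibration

from conftest import make_trace


def brute_force_investigating(d_mm, rule):
    """Independent frame-by-frame application of the investigation rule."""
    n = len(d_mm)
    w = rule.motion_window_frames
    labels = []
    for k in range(n):
        lo = max(0, min(k - w // 2, n - 1))
        hi = max(0, min(k + (w - w // 2), n - 1))
        disp = d_mm[hi] - d_mm[lo]
        if disp < -rule.motion_epsilon_mm:
            labels.append(TOWARD)
        elif disp > rule.motion_epsilon_mm:
            labels.append(AWAY)
        else:
            labels.append(STATIONARY)
    out = []
    last_moving = STATIONARY
    for k in range(n):
        if labels[k] != STATIONARY:
            last_moving = labels[k]
        in_zone = rule.inner_mm <= d_mm[k] <= rule.outer_mm
        out.append(in_zone and last_moving == TOWARD)
    return np.array(out)


class TestCalibrationConversion:
    @pytest.mark.parametrize("cm,expected", [(2, 44), (6, 132)])
    def test_study_calibration_thresholds(self, cm, expected):
        assert cm_to_px(cm, 0.458) == expected

    def test_zero_distance(self):
        assert cm_to_px(0, 0.458) == 0

    def test_exact_multiples_do_not_round_up(self):
        assert cm_to_px(1, 0.5) == 20

    def test_non_positive_calibration_rejected(self):
        with pytest.raises(ScoringError):
            cm_to_px(2, 0)

    def test_zone_rule_pixel_views(self):
        rule = ZoneRule()
        assert rule.inner_px(0.458) == 44
        assert rule.outer_px(0.458) == 132


class TestDistanceFromPrimary:
    def test_frame_at_reference_is_zero(self, calibration):
        trace = make_trace([0.0], calibration)
        assert distance_from_primary(trace)[0] == 0.0

    def test_100px_along_axis(self, calibration):
        trace = make_trace([45.8], calibration)  # 100 px * 0.458 mm/px
        assert distance_from_primary(trace)[0] == pytest.approx(45.8)

    def test_matches_brute_force_projection_with_flipped_axis(self):
        cal = TrackingCalibration(mm_per_pixel=0.5, avg_fps=30,
                                  primary_coord_px=300.0, primary_axis="x",
                                  primary_direction=-1)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 320, size=50)
        from ohdkit.telemetry import TrackingTrace
        trace = TrackingTrace(np.arange(50), x, np.zeros(50), cal)
        expected = np.clip((x - 300.0) * -1, 0, None) * 0.5
        assert np.allclose(distance_from_primary(trace), expected)


class TestMotionLabels:
    def test_strictly_decreasing_is_all_toward(self):
        d = np.linspace(100, 20, 50)  # shrinks ~11 mm per 7-frame window
        labels = motion_labels(d, ZoneRule())
        assert (labels == TOWARD).all()

    def test_constant_distance_is_all_stationary(self):
        labels = motion_labels(np.full(30, 40.0), ZoneRule())
        assert (labels == STATIONARY).all()

    def test_zigzag_matches_brute_force_windows(self):
        rng = np.random.default_rng(9)
        d = 60 + np.cumsum(rng.normal(0, 3, size=200))
        rule = ZoneRule()
        got = motion_labels(d, rule)
        n, w = len(d), rule.motion_window_frames
        for k in range(n):
            lo = max(0, k - w // 2)
            hi = min(n - 1, k + (w - w // 2))
            disp = d[hi] - d[lo]
            expected = (TOWARD if disp < -rule.motion_epsilon_mm
                        else AWAY if disp > rule.motion_epsilon_mm else STATIONARY)
            assert got[k] == expected


class TestDetectBouts:
    def test_secondary_end_trace_has_no_bouts(self, calibration):
        trace = make_trace(np.full(100, 120.0), calibration)  # > 60 mm zone
        assert detect_bouts(trace, ZoneRule()) == []

    def test_entering_zone_while_moving_away_does_not_count(self, calibration):
        d = np.linspace(10, 40, 60)  # outward through the zone
        trace = make_trace(d, calibration)
        assert detect_bouts(trace, ZoneRule()) == []

    def test_approach_then_stationary_counts_from_first_in_zone_toward_frame(
            self, calibration):
        d = np.concatenate([np.linspace(80, 30, 50), np.full(60, 30.0)])
        trace = make_trace(d, calibration)
        rule = ZoneRule()
        bouts = detect_bouts(trace, rule)
        assert len(bouts) == 1
        mask = brute_force_investigating(d, rule)
        first = np.flatnonzero(mask)[0]
        assert bouts[0].start_s == pytest.approx(first / 30)
        assert bouts[0].end_s == pytest.approx(len(d) / 30)  # runs to trace end

    def test_turning_away_rule_inside_inner_boundary(self, calibration):
        # approach into the zone then past the inner boundary: the <2 cm
        # segment must not count even though the motion is still "toward"
        d = np.linspace(80, 5, 80)
        trace = make_trace(d, calibration)
        rule = ZoneRule()
        for b in detect_bouts(trace, rule):
            i0 = int(round(b.start_s * 30))
            i1 = int(round(b.end_s * 30))
            assert (d[i0:i1] >= rule.inner_mm - 1e-9).all()

    def test_min_bout_duration_filter(self, calibration):
        d = np.concatenate([np.linspace(80, 30, 40), np.full(5, 30.0),
                            np.linspace(30, 80, 40), np.full(40, 80.0)])
        trace = make_trace(d, calibration)
        short = detect_bouts(trace, ZoneRule())
        assert len(short) >= 1
        assert detect_bouts(trace, ZoneRule(min_bout_s=10.0)) == []

    @given(seed=hst.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_classifier_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 300))
        # mean-reverting-ish random walk spanning the tube
        d = np.abs(75 + np.cumsum(rng.normal(0, rng.uniform(1, 6), size=n)))
        cal = TrackingCalibration(mm_per_pixel=0.458, avg_fps=30)
        trace = make_trace(d, cal)
        rule = ZoneRule(motion_window_frames=int(rng.integers(1, 12)),
                        motion_epsilon_mm=float(rng.uniform(0.5, 4)))
        got = investigating_frames(trace, rule)
        expected = brute_force_investigating(distance_from_primary(trace), rule)
        assert np.array_equal(got, expected)

    def test_enlarging_outer_boundary_never_decreases_investigation(self, calibration):
        rng = np.random.default_rng(4)
        d = np.abs(70 + np.cumsum(rng.normal(0, 4, size=2000)))
        trace = make_trace(d, calibration)
        totals = []
        for outer in (4.0, 6.0, 8.0, 10.0):
            bouts = detect_bouts(trace, ZoneRule(outer_cm=outer))
            totals.append(sum(b.duration_s for b in bouts))
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))


class TestFramesToSeconds:
    @pytest.mark.parametrize("n,fps,expected", [
        (30, 30, 1.0), (0, 30, 0.0), (45, 29.97, 45 / 29.97)])
    def test_conversion(self, n, fps, expected):
        assert frames_to_seconds(n, fps) == pytest.approx(expected)

    def test_non_positive_fps_rejected(self):
        with pytest.raises(ScoringError):
            frames_to_seconds(10, 0)


class TestScoreTrials:
    def _windows(self, n=3):
        return [TrialWindow(i, 1, i * 120.0, i * 120.0 + 60, (i + 1) * 120.0,
                            "NSA", i + 1) for i in range(n)]

    def test_no_bouts_scores_all_zero(self):
        scores = score_trials([], self._windows(), "S1")
        assert [s.duration_s for s in scores] == [0.0, 0.0, 0.0]

    def test_bout_inside_one_trial(self):
        bouts = [InvestigationBout(130.0, 140.0)]
        scores = score_trials(bouts, self._windows(), "S1")
        assert [s.duration_s for s in scores] == [0.0, 10.0, 0.0]

    def test_boundary_straddling_bout_is_split(self):
        bouts = [InvestigationBout(115.0, 125.0)]
        scores = score_trials(bouts, self._windows(), "S1")
        assert scores[0].duration_s == pytest.approx(5.0)
        assert scores[1].duration_s == pytest.approx(5.0)

    def test_matches_interval_intersection_oracle(self):
        rng = np.random.default_rng(21)
        starts = np.sort(rng.uniform(0, 350, size=40))
        bouts = []
        t = 0.0
        for s in starts:
            if s <= t:
                continue
            e = s + rng.uniform(0.1, 8.0)
            bouts.append(InvestigationBout(float(s), float(e)))
            t = e
        windows = self._windows()
        scores = score_trials(bouts, windows, "S1")
        for w, sc in zip(windows, scores):
            expected = sum(max(0.0, min(b.end_s, w.t_end_s) - max(b.start_s, w.t_start_s))
                           for b in bouts)
            assert sc.duration_s == pytest.approx(expected)
            assert sc.duration_s <= w.duration_s + 1e-9

    def test_overlapping_bouts_rejected(self):
        bouts = [InvestigationBout(0.0, 10.0), InvestigationBout(5.0, 15.0)]
        with pytest.raises(ScoringError):
            score_trials(bouts, self._windows(), "S1")

    def test_scores_carry_stimulus_and_presentation(self, windows):
        bouts = [InvestigationBout(370.0, 380.0)]  # inside NSA presentation 1
        scores = score_trials(bouts, windows, "S7", session="2", method="auto")
        hit = [s for s in scores if s.duration_s > 0]
        assert len(hit) == 1
        assert (hit[0].stimulus, hit[0].presentation) == ("NSA", 1)
        assert (hit[0].subject, hit[0].session) == ("S7", "2")


class TestManualImport:
    def test_empty_annotation(self):
        assert import_manual_bouts([]) == []

    def test_rows_sorted_and_tagged_manual(self):
        bouts = import_manual_bouts([(20.0, 25.0), (3.0, 8.0)])
        assert [(b.start_s, b.end_s) for b in bouts] == [(3.0, 8.0), (20.0, 25.0)]
        assert all(b.source == "manual" for b in bouts)

    def test_overlapping_rows_merged_to_interval_union(self):
        rng = np.random.default_rng(13)
        rows = [(float(s), float(s + rng.uniform(0.5, 10)))
                for s in rng.uniform(0, 100, size=30)]
        bouts = import_manual_bouts(rows)
        # oracle: 0.1 s grid membership in the union of rows
        grid = np.arange(0, 120, 0.1) + 0.05
        in_rows = np.zeros(len(grid), dtype=bool)
        for s, e in rows:
            in_rows |= (grid >= s) & (grid < e)
        in_bouts = np.zeros(len(grid), dtype=bool)
        for b in bouts:
            in_bouts |= (grid >= b.start_s) & (grid < b.end_s)
        assert np.array_equal(in_rows, in_bouts)
        for a, b in zip(bouts, bouts[1:]):
            assert b.start_s > a.end_s

    def test_inverted_row_rejected(self):
        with pytest.raises(ScoringError, match="row"):
            import_manual_bouts([(5.0, 5.0)])

    def test_manual_bouts_flow_through_score_trials(self, windows):
        bouts = import_manual_bouts([(365.0, 372.0)])
        scores = score_trials(bouts, windows, "S1", method="manual")
        assert sum(s.duration_s for s in scores) == pytest.approx(7.0)
        assert all(s.method == "manual" for s in scores)
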