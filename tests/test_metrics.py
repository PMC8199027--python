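"""Tests of the kinematic metric suite, with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hyotrack.metrics import (
    UnitCalibration,
    ae,
    aggregate,
    center_error,
    convert_px_mm,
    evaluate_sequence,
    pearson_axis,
    precision_at,
    precision_curve,
    rmse,
    rom,
    rom_relative_error,
    round_mm_display,
)
from hyotrack.trace import GroundTruthTrack, Trace

finite = st.floats(-1e3, 1e3, allow_nan=False)
point_arrays = arrays(np.float64, (10, 2), elements=finite)


class TestCenterError:
    def test_identical_all_zero(self, rng):
        pts = rng.random((7, 2)) * 100
        assert np.all(center_error(pts, pts) == 0)

    def test_3_4_5(self):
        assert center_error([[3.0, 4.0]], [[0.0, 0.0]])[0] == pytest.approx(5.0)

    def test_single_frame(self):
        assert center_error([[1, 1]], [[1, 2]]).shape == (1,)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            center_error(np.zeros((3, 2)), np.zeros((4, 2)))

    @given(point_arrays, point_arrays)
    @settings(max_examples=25, deadline=None)
    def test_symmetric_in_arguments(self, a, b):
        assert np.allclose(center_error(a, b), center_error(b, a))

    @given(point_arrays, point_arrays, st.tuples(finite, finite))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariant(self, a, b, shift):
        s = np.array(shift)
        assert np.allclose(center_error(a + s, b + s), center_error(a, b), atol=1e-6)


class TestPrecision:
    def test_hand_counted(self):
        assert precision_at(np.array([3.0, 6.0, 12.0]), 5.0) == pytest.approx(1 / 3)

    def test_infinite_threshold(self):
        assert precision_at(np.array([3.0, 6.0, 12.0]), np.inf) == 1.0

    def test_boundary_inclusive(self):
        assert precision_at(np.zeros(5), 0.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            precision_at(np.array([]), 5.0)

    def test_curve_hand_case(self):
        curve = precision_curve(np.array([3.0, 6.0, 12.0]), [5.0, 10.0, 15.0])
        assert np.allclose(curve[:, 1], [1 / 3, 2 / 3, 1.0])

    def test_curve_step_at_constant(self):
        curve = precision_curve(np.full(4, 7.0), [6.0, 7.0, 8.0])
        assert np.allclose(curve[:, 1], [0.0, 1.0, 1.0])

    def test_duplicate_thresholds_equal_values(self):
        curve = precision_curve(np.array([1.0, 9.0]), [5.0, 5.0])
        assert curve[0, 1] == curve[1, 1]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            precision_curve(np.ones(3), [5.0, 1.0])

    @given(arrays(np.float64, 20, elements=st.floats(0, 100)))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, delta):
        curve = precision_curve(delta, np.linspace(0, 120, 25))
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert np.all((curve[:, 1] >= 0) & (curve[:, 1] <= 1))


class TestRmseAe:
    def test_hand_arithmetic(self):
        delta = np.array([3.0, 4.0])
        assert rmse(delta) == pytest.approx(np.sqrt(12.5))
        assert ae(delta) == pytest.approx(3.5)

    def test_constant_series(self):
        delta = np.full(9, 2.5)
        assert rmse(delta) == pytest.approx(2.5)
        assert ae(delta) == pytest.approx(2.5)

    @given(arrays(np.float64, 15, elements=st.floats(0, 1e3)))
    @settings(max_examples=30, deadline=None)
    def test_power_mean_inequality(self, delta):
        assert rmse(delta) >= ae(delta) - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.array([]))
        with pytest.raises(ValueError):
            ae(np.array([]))


class TestPearson:
    def test_identical_is_one(self, rng):
        pts = rng.random((20, 2)) * 50
        assert pearson_axis(pts, pts, "x") == pytest.approx(1.0)

    def test_negated_is_minus_one(self, rng):
        pts = rng.random((20, 2)) * 50
        neg = pts.mean(axis=0) - (pts - pts.mean(axis=0))
        assert pearson_axis(neg, pts, "y") == pytest.approx(-1.0)

    def test_five_point_textbook_oracle(self):
        a = np.column_stack([[1.0, 2, 4, 5, 8], np.zeros(5)])
        b = np.column_stack([[2.0, 3, 5, 4, 9], np.zeros(5)])
        r = pearson_axis(a, b, "x")
        x, y = a[:, 0], b[:, 0]
        ref = (((x - x.mean()) * (y - y.mean())).sum()
               / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_warns_nan(self):
        flat = np.tile([3.0, 4.0], (5, 1))
        other = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="variance"):
            assert np.isnan(pearson_axis(flat, other, "x"))


class TestRom:
    def test_hand_geometry(self):
        track = np.array([[0.0, 0.0], [-15.0, 20.0], [-30.0, 40.0]])
        assert rom(track, 0, 2) == pytest.approx((30.0, 40.0, 50.0))

    def test_static_track_zero(self):
        track = np.tile([5.0, 5.0], (6, 1))
        assert rom(track, 0, 5) == (0.0, 0.0, 0.0)

    @given(arrays(np.float64, (12, 2), elements=finite))
    @settings(max_examples=30, deadline=None)
    def test_line_dominates_axes(self, track):
        rx, ry, rl = rom(track, 0, 11)
        assert rl >= max(rx, ry) - 1e-9

    def test_bad_events_rejected(self):
        with pytest.raises(ValueError):
            rom(np.zeros((5, 2)), 3, 3)

    def test_axis_maxima_may_differ_in_frame(self):
        # x max at frame 1, y max at frame 2; both counted
        track = np.array([[0.0, 0.0], [-10.0, 1.0], [-2.0, 8.0]])
        assert rom(track, 0, 2)[:2] == pytest.approx((10.0, 8.0))


class TestRomRelativeError:
    def test_exact_zero(self):
        assert rom_relative_error(50.0, 50.0) == 0.0

    def test_ten_percent(self):
        assert rom_relative_error(50.0, 45.0) == pytest.approx(10.0)

    def test_symmetric_absolute(self):
        assert rom_relative_error(50.0, 55.0) == pytest.approx(10.0)

    def test_zero_gt_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(rom_relative_error(0.0, 5.0))


class TestCalibration:
    def test_paper_conversions(self):
        cal = UnitCalibration()
        assert round_mm_display(convert_px_mm(10, cal, "px_to_mm")) == 3.25
        assert round_mm_display(convert_px_mm(5, cal, "px_to_mm")) == 1.63

    def test_round_trip_identity(self):
        cal = UnitCalibration()
        v = 17.3
        back = convert_px_mm(convert_px_mm(v, cal, "px_to_mm"), cal, "mm_to_px")
        assert back == pytest.approx(v, rel=1e-9)

    def test_reciprocal_invariant(self):
        cal = UnitCalibration(0.325, 3.078)  # as printed
        assert cal.mm_per_px * cal.px_per_mm == pytest.approx(1.0, abs=1e-3)

    def test_inconsistent_rejected(self):
        with pytest.raises(ValueError):
            UnitCalibration(0.325, 4.0)

    def test_round_half_away_from_zero(self):
        assert round_mm_display(1.625) == 1.63
        assert round_mm_display(2.005) == 2.01


class TestAggregate:
    def _report(self, delta, seq_id="s"):
        n = len(delta)
        gt = np.zeros((n, 2))
        gt[:, 0] = np.linspace(0, -30, n)
        gt[:, 1] = np.linspace(0, 10, n)
        pred = gt + np.column_stack([delta, np.zeros(n)])
        trace = Trace(pred, seq_id)
        track = GroundTruthTrack(gt, {"hyoid_onset": 0, "hyoid_offset": n - 1,
                                      "swallow_end": n - 1})
        return evaluate_sequence(trace, track)

    def test_single_report_sd_zero(self):
        summary = aggregate([self._report(np.ones(8))])
        assert summary["rmse"]["sd"] == 0.0
        assert "sd_note" in summary

    def test_two_precisions_mean(self):
        r1 = self._report(np.full(10, 4.0))  # p@5 = 1.0
        r2 = self._report(np.concatenate([np.full(5, 4.0), np.full(5, 9.0)]))
        summary = aggregate([r1, r2])
        assert summary["precision_at_5"]["mean"] == pytest.approx(0.75)

    def test_sample_sd_hand_check(self):
        reports = [self._report(np.full(6, v)) for v in (1.0, 2.0, 4.0)]
        summary = aggregate(reports)
        vals = np.array([1.0, 2.0, 4.0])
        assert summary["ae"]["mean"] == pytest.approx(vals.mean())
        assert summary["ae"]["sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_pooled_option(self):
        r1 = self._report(np.full(4, 1.0))
        r2 = self._report(np.full(8, 7.0))
        summary = aggregate([r1, r2], pool_frames=True)
        assert summary["pooled"]["precision_at_5"] == pytest.approx(4 / 12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestBruteForceOracle:
    """Independent re-computation of every metric on random inputs."""

    def test_all_metrics_match(self, rng):
        for _ in range(20):
            pred = rng.random((10, 2)) * 100
            gt = rng.random((10, 2)) * 100
            delta = center_error(pred, gt)
            # brute-force, loop-based recomputation
            ref_delta = np.array(
                [
                    np.sqrt((pred[t, 0] - gt[t, 0]) ** 2 + (pred[t, 1] - gt[t, 1]) ** 2)
                    for t in range(10)
                ]
            )
            assert np.allclose(delta, ref_delta, atol=1e-9)
            thr = rng.random() * 100
            ref_prec = sum(1 for d in ref_delta if d <= thr) / 10
            assert abs(precision_at(delta, thr) - ref_prec) <= 1e-9
            assert abs(rmse(delta) - np.sqrt(sum(d * d for d in ref_delta) / 10)) <= 1e-9
            assert abs(ae(delta) - sum(ref_delta) / 10) <= 1e-9
            onset, offset = 2, 8
            rx = max(abs(gt[t, 0] - gt[onset, 0]) for t in range(onset, offset + 1))
            ry = max(abs(gt[t, 1] - gt[onset, 1]) for t in range(onset, offset + 1))
            rl = max(
                np.sqrt((gt[t, 0] - gt[onset, 0]) ** 2 + (gt[t, 1] - gt[onset, 1]) ** 2)
                for t in range(onset, offset + 1)
            )
            assert np.allclose(rom(gt, onset, offset), (rx, ry, rl), atol=1e-9)
            a, b = 1 + rng.random() * 50, 1 + rng.random() * 50
            assert abs(rom_relative_error(a, b) - abs(a - b) / a * 100) <= 1e-9
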