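import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from exerstep.detection import (
    ArmLiftEvent,
    DetectionConfig,
    StepEvent,
    derive_single_support,
    detect_arm_lifts,
    detect_steps,
    estimate_speed,
)
from exerstep.errors import InsufficientData, MarkerSetMismatch

from conftest import RATE, add_step, brute_force_steps, make_recording

#: Near-pass-through differentiation: isolates the printed thresholds from
#: filter smoothing when testing rule boundaries.
RAW_CFG = DetectionConfig(filter_cutoff=55.0)


class TestEstimateSpeed:
    def test_constant_position_zero_speed(self):
        series = np.tile([1.0, -2.0, 0.5], (200, 1))
        speed = estimate_speed(series, RATE)
        np.testing.assert_allclose(speed, 0.0, atol=1e-9)

    def test_uniform_motion_interior(self):
        t = np.arange(600) / RATE
        series = np.column_stack([0.5 * t, np.zeros_like(t), np.ones_like(t)])
        speed = estimate_speed(series, RATE)
        np.testing.assert_allclose(speed[50:-50], 0.5, rtol=1e-3)

    def test_sinusoid_closed_form_envelope(self):
        # x = 0.1 sin(2 pi t): |v| = 0.2 pi |cos(2 pi t)|
        t = np.arange(1200) / RATE
        series = np.column_stack([0.1 * np.sin(2 * np.pi * t),
                                  np.zeros_like(t), np.zeros_like(t)])
        speed = estimate_speed(series, RATE, cutoff=6.0)
        expected = 0.2 * np.pi * np.abs(np.cos(2 * np.pi * t))
        sl = slice(120, -120)
        assert np.max(np.abs(speed[sl] - expected[sl])) < 0.01 * 0.2 * np.pi

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientData):
            estimate_speed(np.zeros((2, 3)), RATE)

    def test_same_length_as_input(self):
        series = np.random.default_rng(0).normal(size=(100, 3))
        assert len(estimate_speed(series, RATE)) == 100


class TestDetectStepsThresholds:
    def _one_burst(self, dx, duration):
        rec = make_recording(int(2.0 * RATE))
        add_step(rec, "toe_L", t0=0.8, duration=duration, dx=dx)
        return rec

    def test_small_displacement_rejected(self):
        # 0.02 m net displacement fails the >= 0.03 m rule
        rec = self._one_burst(0.02, 0.4)
        steps = detect_steps(rec, RAW_CFG)
        assert steps["left"] == [] and steps["right"] == []

    def test_short_burst_rejected(self):
        # above-band time of a 0.03 s burst is < 0.05 s
        rec = self._one_burst(0.035, 0.03)
        steps = detect_steps(rec, RAW_CFG)
        assert steps["left"] == []

    def test_minimally_compliant_burst_accepted(self):
        rec = self._one_burst(0.06, 0.14)
        steps = detect_steps(rec, RAW_CFG)
        assert len(steps["left"]) == 1
        ev = steps["left"][0]
        assert ev.size >= 0.03 and ev.duration >= 0.05

    def test_static_recording_no_steps(self, static_recording):
        steps = detect_steps(static_recording)
        assert steps == {"left": [], "right": []}

    def test_missing_foot_marker_raises(self):
        rec = make_recording(200)
        del rec.positions["toe_R"]
        with pytest.raises(MarkerSetMismatch):
            detect_steps(rec)


class TestDetectStepsOracle:
    def test_single_step_matches_brute_force(self):
        rec = make_recording(int(1.3 * RATE))
        add_step(rec, "toe_R", t0=0.5, duration=0.4, dx=0.25)
        cfg = DetectionConfig()
        speed, filt = estimate_speed(rec["toe_R"], RATE, cfg.filter_cutoff,
                                     return_filtered=True)
        expected = brute_force_steps(speed, filt[:, :2], RATE)
        got = detect_steps(rec, cfg)["right"]
        assert len(got) == len(expected) == 1
        assert got[0].start == pytest.approx(expected[0][0], abs=1.0 / RATE)
        assert got[0].end == pytest.approx(expected[0][1], abs=1.0 / RATE)
        assert got[0].size == pytest.approx(expected[0][2], abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_randomized_series_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rec = make_recording(int(4.0 * RATE))
        t = 0.3
        while t < 3.2:
            dx = rng.uniform(-0.3, 0.3)
            dur = rng.uniform(0.05, 0.5)
            add_step(rec, "toe_L", t0=t, duration=dur, dx=dx,
                     dy=rng.uniform(-0.1, 0.1))
            t += dur + rng.uniform(0.05, 0.4)
        cfg = DetectionConfig()
        speed, filt = estimate_speed(rec["toe_L"], RATE, cfg.filter_cutoff,
                                     return_filtered=True)
        expected = brute_force_steps(speed, filt[:, :2], RATE)
        got = detect_steps(rec, cfg)["left"]
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g.start == pytest.approx(e[0], abs=1e-9)
            assert g.end == pytest.approx(e[1], abs=1e-9)
            assert g.size == pytest.approx(e[2], abs=1e-9)


class TestDetectStepsProperties:
    def _stepped_recording(self, seed):
        rng = np.random.default_rng(seed)
        rec = make_recording(int(3.0 * RATE))
        for t0 in (0.4, 1.2, 2.0):
            add_step(rec, "toe_L", t0=t0, duration=rng.uniform(0.2, 0.4),
                     dx=rng.uniform(0.05, 0.3))
        return rec

    @pytest.mark.parametrize("seed", range(4))
    def test_monotonicity_in_thresholds(self, seed):
        rec = self._stepped_recording(seed)
        base = detect_steps(rec, DetectionConfig())
        stricter_disp = detect_steps(rec, DetectionConfig(min_displacement=0.12))
        stricter_dur = detect_steps(rec, DetectionConfig(min_duration=0.25))
        for foot in ("left", "right"):
            assert len(stricter_disp[foot]) <= len(base[foot])
            assert len(stricter_dur[foot]) <= len(base[foot])

    def test_translation_invariance(self):
        rec = self._stepped_recording(11)
        moved = make_recording(rec.n_frames)
        for name in rec.positions:
            moved.positions[name] = rec.positions[name] + np.array([3.0, -2.0, 0.0])
        a = detect_steps(rec)["left"]
        b = detect_steps(moved)["left"]
        assert [(e.start, e.end) for e in a] == [(e.start, e.end) for e in b]
        np.testing.assert_allclose([e.size for e in a], [e.size for e in b],
                                   atol=1e-12)

    def test_rotation_about_z_invariance(self):
        rec = self._stepped_recording(12)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        rot = make_recording(rec.n_frames)
        for name in rec.positions:
            rot.positions[name] = rec.positions[name] @ R.T
        a = detect_steps(rec)["left"]
        b = detect_steps(rot)["left"]
        assert len(a) == len(b)
        np.testing.assert_allclose([e.size for e in a], [e.size for e in b],
                                   atol=1e-9)


def _square_lift(rec, side, start, end, height=1.75):
    tag = "L" if side == "left" else "R"
    arr = rec.positions[f"wrist_{tag}"].copy()
    i0, i1 = int(start * rec.rate), int(end * rec.rate)
    arr[i0:i1, 2] = height
    rec.positions[f"wrist_{tag}"] = arr


class TestDetectArmLifts:
    # mean head height of the fixture posture is 1.60 m

    def test_wrist_below_head_no_events(self, static_recording):
        assert detect_arm_lifts(static_recording) == []

    def test_single_excursion_boundaries(self):
        rec = make_recording(int(3.0 * RATE))
        _square_lift(rec, "left", 1.0, 1.8)
        events = detect_arm_lifts(rec)
        assert len(events) == 1
        ev = events[0]
        assert ev.side == "left"
        assert ev.start == pytest.approx(1.0, abs=2.0 / RATE)
        assert ev.end == pytest.approx(1.8, abs=2.0 / RATE)

    def test_two_excursions_crossing_scan_oracle(self):
        rec = make_recording(int(4.0 * RATE))
        _square_lift(rec, "right", 0.5, 1.0)
        _square_lift(rec, "right", 2.0, 2.4)
        events = detect_arm_lifts(rec)
        assert len(events) == 2
        # independent crossing scan on the raw series
        head_z = np.mean([rec[h][:, 2] for h in rec.markers.head], axis=0)
        z = rec["wrist_R"][:, 2]
        above = z > head_z
        n_cross = int(np.sum(np.diff(above.astype(int)) == 1))
        assert n_cross == 2

    def test_short_chatter_discarded(self):
        rec = make_recording(int(2.0 * RATE))
        _square_lift(rec, "left", 1.0, 1.05)     # 0.05 s < min_lift_duration
        assert detect_arm_lifts(rec) == []

    def test_bilateral_merged_to_both(self):
        rec = make_recording(int(3.0 * RATE))
        _square_lift(rec, "left", 1.0, 1.8)
        _square_lift(rec, "right", 1.1, 1.9)
        events = detect_arm_lifts(rec)
        assert len(events) == 1
        assert events[0].side == "both"

    def test_missing_wrist_raises(self):
        rec = make_recording(100)
        del rec.positions["wrist_L"]
        with pytest.raises(MarkerSetMismatch):
            detect_arm_lifts(rec)


class TestDeriveSingleSupport:
    def test_no_steps_no_support(self):
        out = derive_single_support({"left": [], "right": []}, 10.0)
        assert out == {"left": [], "right": []}

    def test_single_swing_supports_contralateral(self):
        steps = {"left": [],
                 "right": [StepEvent("right", 2.0, 2.5, 0.2)]}
        out = derive_single_support(steps, 10.0)
        assert out["left"] == [type(out["left"][0])("left", 2.0, 2.5)]
        assert out["left"][0].duration == pytest.approx(0.5)
        assert out["right"] == []

    def test_double_swing_overlap_excluded(self):
        steps = {"right": [StepEvent("right", 2.0, 2.5, 0.2)],
                 "left": [StepEvent("left", 2.4, 2.9, 0.2)]}
        out = derive_single_support(steps, 10.0)
        (lv,) = out["left"]
        (rv,) = out["right"]
        assert (lv.start, lv.end) == (2.0, 2.4)
        assert (rv.start, rv.end) == (2.5, 2.9)
        assert lv.duration == pytest.approx(0.4)
        assert rv.duration == pytest.approx(0.4)

    def test_intervals_clipped_to_duration(self):
        steps = {"left": [], "right": [StepEvent("right", 9.8, 10.6, 0.1)]}
        out = derive_single_support(steps, 10.0)
        assert out["left"][0].end == pytest.approx(10.0)

    @given(st.lists(st.tuples(st.floats(0, 8), st.floats(0.1, 1.5)),
                    min_size=0, max_size=6))
    @hyp_settings(max_examples=50, deadline=None)
    def test_support_never_overlaps_own_steps(self, raw):
        rights = []
        t = 0.0
        for gap, dur in raw:
            start = t + gap
            rights.append(StepEvent("right", start, start + dur, 0.1))
            t = start + dur + 0.01
        lefts = [StepEvent("left", s.start + 0.3, s.end + 0.3, 0.1)
                 for s in rights[::2]]
        out = derive_single_support({"left": lefts, "right": rights}, t + 5)
        for iv in out["left"]:
            for s in lefts:
                assert iv.end <= s.start or iv.start >= s.end
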