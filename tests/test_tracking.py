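"""Tail/eye tracking: render-and-recover, bout detection, degenerate inputs."""

import numpy as np
import pytest

from ototrap import synthetic, tracking
from ototrap.synthetic import FrameGeometry, render_frames
from ototrap.tracking import (
    detect_bouts,
    detect_eye_landmarks,
    extract_tail_midline,
    eye_rotation,
    tail_deflection_angle,
    track_tail,
)

GEOM = FrameGeometry()
AXIS = (
    GEOM.swim_bladder_px[0] - GEOM.head_px[0],
    GEOM.swim_bladder_px[1] - GEOM.head_px[1],
)


class TestMidline:
    def test_straight_tail_midline_is_collinear_with_axis(self):
        stack, _ = render_frames([0.0, 0.0], GEOM, seed=1)
        mid, ok = extract_tail_midline(
            stack.frames[0], GEOM.head_px, GEOM.swim_bladder_px
        )
        assert ok
        # perpendicular residual from the body-axis line (y = 150)
        assert np.abs(mid[:, 1] - GEOM.head_px[1]).max() < 1.0

    def test_arc_tail_angle_recovered_within_one_degree(self):
        stack, _ = render_frames([20.0, 20.0], GEOM, seed=2)
        mid, ok = extract_tail_midline(
            stack.frames[0], GEOM.head_px, GEOM.swim_bladder_px
        )
        assert ok
        assert tail_deflection_angle(mid, AXIS) == pytest.approx(20.0, abs=1.0)

    def test_blank_frame_flags_failure_without_crash(self):
        rng = np.random.default_rng(0)
        blank = rng.normal(200, 4, (300, 600)).astype(np.uint8)
        mid, ok = extract_tail_midline(blank, GEOM.head_px, GEOM.swim_bladder_px)
        assert not ok

    def test_mirror_flip_negates_angle(self):
        stack, _ = render_frames([15.0, 15.0], GEOM, seed=3)
        frame = stack.frames[0]
        flipped = frame[::-1]
        h = frame.shape[0]
        head_f = (GEOM.head_px[0], h - 1 - GEOM.head_px[1])
        sb_f = (GEOM.swim_bladder_px[0], h - 1 - GEOM.swim_bladder_px[1])
        mid, _ = extract_tail_midline(frame, GEOM.head_px, GEOM.swim_bladder_px)
        mid_f, _ = extract_tail_midline(flipped, head_f, sb_f)
        a = tail_deflection_angle(mid, AXIS)
        a_f = tail_deflection_angle(mid_f, (AXIS[0], -AXIS[1]))
        assert a_f == pytest.approx(-a, abs=0.3)


class TestDeflectionAngle:
    def test_straight_midline_is_zero(self):
        mid = np.column_stack([np.linspace(0, 100, 20), np.zeros(20)])
        assert tail_deflection_angle(mid, (1.0, 0.0)) == 0.0

    def test_mirrored_midline_negates(self):
        rng = np.random.default_rng(1)
        y = np.cumsum(rng.normal(0.5, 0.2, 20))
        mid = np.column_stack([np.linspace(0, 100, 20), y])
        mirrored = mid * np.array([1.0, -1.0])
        a = tail_deflection_angle(mid, (1.0, 0.0))
        assert tail_deflection_angle(mirrored, (1.0, 0.0)) == pytest.approx(-a)

    def test_sweep_recovered_with_sub_degree_rmse(self):
        angles = np.linspace(-40, 40, 9)
        stack, _ = render_frames(angles, GEOM, seed=4)
        trace = track_tail(stack)
        assert not trace.failed.any()
        rmse = np.sqrt(np.mean((trace.deflection_deg - angles) ** 2))
        assert rmse < 1.0


class TestBouts:
    FR = 200.0

    def _trace(self, n=400):
        return np.zeros(n)

    def test_pure_sinusoid_gives_exactly_one_bout(self):
        t = np.arange(0, 2.0, 1 / self.FR)
        x = np.where((t >= 0.75) & (t < 1.25), 15 * np.sin(2 * np.pi * 20 * t), 0.0)
        bouts = detect_bouts(x, self.FR)
        assert len(bouts) == 1
        assert bouts[0].onset_s == pytest.approx(0.75, abs=0.05)  # within 1 cycle
        assert bouts[0].dominant_freq_hz == pytest.approx(20.0, rel=0.15)
        assert bouts[0].classification == "swim"

    def test_slow_ramp_and_hold_is_not_a_bout(self):
        t = np.arange(0, 3.0, 1 / self.FR)
        x = np.clip((t - 1.0) * 20.0, 0.0, 15.0)  # ramp to 15 deg, hold
        assert detect_bouts(x, self.FR) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_no_false_positives_on_noisy_ramps(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 3.0, 1 / self.FR)
        x = np.clip((t - 1.0) * 20.0, 0.0, 15.0) + rng.normal(0, 2.0, t.size)
        assert detect_bouts(x, self.FR) == []

    def test_bout_on_ramp_detected_and_maskable(self):
        from ototrap.trialstats import mask_bouts

        t = np.arange(0, 3.0, 1 / self.FR)
        ramp = np.clip((t - 0.5) * 10.0, 0.0, 18.0)
        osc = np.where(
            (t >= 1.5) & (t < 2.0), 12 * np.sin(2 * np.pi * 20 * (t - 1.5)), 0.0
        )
        bouts = detect_bouts(ramp + osc, self.FR)
        assert len(bouts) == 1
        masked = mask_bouts(t, ramp + osc, bouts)
        assert np.abs(masked - ramp).max() < 2.0  # underlying posture preserved

    def test_violent_oscillation_classified_as_escape(self):
        t = np.arange(0, 1.0, 1 / self.FR)
        x = np.where((t >= 0.3) & (t < 0.5), 35 * np.sin(2 * np.pi * 35 * t), 0.0)
        bouts = detect_bouts(x, self.FR, escape_velocity_dps=3000.0)
        assert len(bouts) == 1
        assert bouts[0].classification == "escape"


class TestEyeRotation:
    def _landmarks(self, rot_left, rot_right, n=5):
        return np.stack(
            [
                synthetic._eye_landmarks(GEOM, (rot_left, rot_right))
                for _ in range(n)
            ]
        )

    def test_rotated_landmarks_give_that_angle(self):
        lm = self._landmarks(10.0, 10.0)
        trace = eye_rotation(lm, AXIS, 200.0)
        np.testing.assert_allclose(trace.left_deg, 10.0, atol=1e-9)
        np.testing.assert_allclose(trace.right_deg, 10.0, atol=1e-9)

    def test_no_rotation_gives_flat_zero(self):
        trace = eye_rotation(self._landmarks(0.0, 0.0), AXIS, 200.0)
        np.testing.assert_allclose(trace.left_deg, 0.0, atol=1e-9)

    def test_baseline_subtraction(self):
        lm = np.concatenate(
            [self._landmarks(2.0, 2.0, 10), self._landmarks(12.0, 12.0, 10)]
        )
        trace = eye_rotation(lm, AXIS, 10.0, baseline_window_s=(0.0, 1.0))
        np.testing.assert_allclose(trace.left_deg[:10], 0.0, atol=1e-9)
        np.testing.assert_allclose(trace.left_deg[10:], 10.0, atol=1e-9)

    def test_missing_landmark_flags_frame(self):
        lm = self._landmarks(5.0, 5.0)
        lm[2, 0, 1] = np.nan
        trace = eye_rotation(lm, AXIS, 200.0)
        assert trace.flagged[2]
        assert np.isnan(trace.left_deg[2])
        assert not trace.flagged[[0, 1, 3, 4]].any()

    def test_render_and_recover_eye_sweep_sub_half_degree(self):
        rolls = np.linspace(-10, 10, 9)
        eyes = np.column_stack([rolls, rolls])
        stack, _ = render_frames(np.zeros(9), GEOM, eye_angles_deg=eyes, seed=6)
        lm = np.array(
            [detect_eye_landmarks(f, GEOM.eye_centres_px) for f in stack.frames]
        )
        trace = eye_rotation(lm, AXIS, GEOM.frame_rate_hz)
        err = np.concatenate([trace.left_deg - rolls, trace.right_deg - rolls])
        assert np.sqrt(np.nanmean(err**2)) < 0.5

    def test_unison_roll_gives_matching_traces(self):
        rolls = np.linspace(0, 8, 6)
        stack, _ = render_frames(
            np.zeros(6), GEOM, eye_angles_deg=np.column_stack([rolls, rolls]),
            seed=7,
        )
        lm = np.array(
            [detect_eye_landmarks(f, GEOM.eye_centres_px) for f in stack.frames]
        )
        trace = eye_rotation(lm, AXIS, GEOM.frame_rate_hz)
        np.testing.assert_allclose(trace.left_deg, trace.right_deg, atol=0.5)
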