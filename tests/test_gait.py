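import numpy as np
import pytest

from gaitrec import (
    GaitEvents,
    angle_based_parameters,
    assemble_parameter_vector,
    basic_parameters,
    compute_parameter_vector,
    detect_gait_events,
    mirror_sequence,
    phase_parameters,
)
from gaitrec.errors import InsufficientGaitCyclesError, ValidationError
from gaitrec.gait import PARAMETER_LABELS, GaitParameterVector
from gaitrec.skeleton import SkeletonSequence
from gaitrec.synth import SubjectProfile, simulate_walk, style_for_class


def _oscillating_sequence(joints, n_frames=100, fps=30.0, amp=0.3, period_s=1.0,
                          peak_frame=10):
    """Ankle-minus-pelvis forward signal is an exact cosine per side."""
    pos = np.zeros((n_frames, joints.n_joints, 3))
    pos[:, :, 1] = np.linspace(0.1, 1.6, joints.n_joints)[None, :]
    pos[:, joints.index("hip_left"), 0] = 0.1
    pos[:, joints.index("hip_right"), 0] = -0.1
    t = np.arange(n_frames)
    phase = 2.0 * np.pi * (t - peak_frame) / (period_s * fps)
    pos[:, joints.index("ankle_left"), 2] = amp * np.cos(phase)
    pos[:, joints.index("ankle_right"), 2] = -amp * np.cos(phase)
    pos[:, joints.index("ankle_left"), 0] = 0.1
    pos[:, joints.index("ankle_right"), 0] = -0.1
    return SkeletonSequence(joints, pos, fps=fps)


class TestEventDetection:
    def test_sinusoid_strikes_at_maxima(self, joints):
        seq = _oscillating_sequence(joints)
        ev = detect_gait_events(seq)
        for got, expected in zip(ev.heel_strikes_left, [10, 40, 70]):
            assert abs(got - expected) <= 1
        for got, expected in zip(ev.toe_offs_left, [25, 55, 85]):
            assert abs(got - expected) <= 1

    def test_static_skeleton_insufficient_cycles(self, static_sequence):
        with pytest.raises(InsufficientGaitCyclesError, match="insufficient"):
            detect_gait_events(static_sequence)

    def test_simulator_events_matched_within_2_frames(self, subject):
        """At default sensor noise, >= 90% of ground-truth events are found."""
        matched = total = 0
        for cls in ("normal", "antalgic", "steppage", "trendelenburg"):
            style = style_for_class(cls, subject.affected_side,
                                    scale=subject.step_scale)
            seq, gt = simulate_walk(style, subject, 120, 30.0, seed=3,
                                    noise_std=0.003)
            ev = detect_gait_events(seq)
            for side in ("left", "right"):
                for kind, detected in (("heel_strikes", ev.strikes(side)),
                                       ("toe_offs", ev.toe_offs(side))):
                    for true_frame in gt[f"{kind}_{side}"]:
                        total += 1
                        if any(abs(true_frame - d) <= 2 for d in detected):
                            matched += 1
        assert matched / total >= 0.90

    def test_event_lists_strictly_increasing(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            GaitEvents([5, 5], [1, 2], [3], [4])


class TestBasicParameters:
    def test_symmetric_gait_zero_asymmetry(self, joints):
        seq = _oscillating_sequence(joints)
        ev = detect_gait_events(seq)
        out = basic_parameters(seq, ev)
        assert out["step_length_asymmetry"] == pytest.approx(0.0, abs=1e-9)

    def test_pelvis_2m_over_2s_speed_1(self, joints):
        seq = _oscillating_sequence(joints, n_frames=61, fps=30.0)
        seq.positions[:, joints.index("pelvis"), 2] = np.linspace(0, 2.0, 61)
        ev = detect_gait_events(seq)
        out = basic_parameters(seq, ev)
        assert out["walking_speed"] == pytest.approx(1.0, abs=1e-9)

    def test_commanded_step_lengths_recovered(self, subject):
        """Commanded 0.5 / 0.4 m steps: avg ~ 0.45, asymmetry ~ 0.222."""
        style = style_for_class("normal", "left")
        style = type(style)(**{**style.__dict__, "step_length": (0.5, 0.4)})
        # long, high-rate walk: step asymmetry is a ratio of differences and
        # needs sub-frame event timing precision
        seq, gt = simulate_walk(style, subject, 1200, 60.0, seed=4,
                                noise_std=0.0)
        assert gt["step_length_left"] == pytest.approx(0.5, rel=1e-6)
        assert gt["step_length_right"] == pytest.approx(0.4, rel=1e-6)
        ev = detect_gait_events(seq)
        out = basic_parameters(seq, ev)
        assert out["avg_step_length"] == pytest.approx(0.45, rel=0.05)
        assert out["step_length_asymmetry"] == pytest.approx(2 * 0.1 / 0.9,
                                                             rel=0.05)

    def test_zero_elapsed_time_error(self, joints):
        seq = _oscillating_sequence(joints)
        ev = detect_gait_events(seq)
        frozen = SkeletonSequence(joints, seq.positions, fps=30.0,
                                  frame_timestamps=np.zeros(seq.n_frames))
        with pytest.raises(ValidationError, match="elapsed"):
            basic_parameters(frozen, ev)


class TestPhaseParameters:
    def test_hand_arithmetic(self):
        ev = GaitEvents(heel_strikes_left=[0, 30], toe_offs_left=[18],
                        heel_strikes_right=[15, 45], toe_offs_right=[33])
        out = phase_parameters(ev, fps=30.0)
        assert out["stance_time_left"] == pytest.approx(0.6)
        assert out["swing_time_left"] == pytest.approx(0.4)

    def test_symmetric_trains_equal_sides(self):
        ev = GaitEvents([0, 30, 60], [15, 45, 75], [18, 48], [33, 63])
        out = phase_parameters(ev, 30.0)
        assert out["stance_time_left"] == pytest.approx(out["stance_time_right"])
        assert out["swing_time_left"] == pytest.approx(out["swing_time_right"])

    def test_non_alternating_rejected(self):
        ev = GaitEvents([0, 10, 30], [5, 35], [18], [25])
        with pytest.raises(ValidationError, match="non-alternating"):
            phase_parameters(ev, 30.0)

    def test_stance_plus_swing_is_cycle(self, subject):
        """stance + swing per side ~ mean cycle duration within one frame."""
        style = style_for_class("normal", "left", scale=subject.step_scale)
        seq, gt = simulate_walk(style, subject, 300, 30.0, seed=5,
                                noise_std=0.0)
        ev = detect_gait_events(seq)
        out = phase_parameters(ev, seq.fps)
        for side in ("left", "right"):
            strikes = ev.strikes(side)
            cycle = np.mean(np.diff(strikes)) / seq.fps
            total = out[f"stance_time_{side}"] + out[f"swing_time_{side}"]
            assert abs(total - cycle) <= 1.5 / seq.fps


class TestAngleBasedParameters:
    def test_vertical_static_trunk_zero_spine_angles(self, static_sequence):
        out = angle_based_parameters(static_sequence)
        for key in ("frontal_spine_mean", "frontal_spine_max",
                    "lateral_spine_mean", "lateral_spine_max"):
            assert out[key] == pytest.approx(0.0, abs=1e-9)

    def test_constant_knee_angle(self, joints):
        pos = np.zeros((10, joints.n_joints, 3))
        pos[:, :, 1] = np.linspace(0.05, 1.6, joints.n_joints)[None, :]
        # left knee at 170 degrees: hip straight up, ankle 10 deg off vertical
        pos[:, joints.index("knee_left")] = (0.1, 0.5, 0.0)
        pos[:, joints.index("hip_left")] = (0.1, 0.9, 0.0)
        ang = np.radians(10.0)
        pos[:, joints.index("ankle_left")] = (
            0.1, 0.5 - 0.4 * np.cos(ang), 0.4 * np.sin(ang))
        seq = SkeletonSequence(joints, pos)
        out = angle_based_parameters(seq)
        for stat in ("mean", "min", "max"):
            assert out[f"knee_left_{stat}"] == pytest.approx(170.0, abs=1e-6)

    def test_lateral_tilt_10_degrees(self, static_sequence):
        seq = static_sequence.copy()
        pelvis = seq.positions[0, seq.joints.index("pelvis")]
        head_idx = seq.joints.index("head")
        trunk_len = np.linalg.norm(seq.positions[0, head_idx] - pelvis)
        tilt = np.radians(10.0)
        seq.positions[:, head_idx] = pelvis + trunk_len * np.array(
            [np.sin(tilt), np.cos(tilt), 0.0])
        out = angle_based_parameters(seq)
        assert out["frontal_spine_mean"] == pytest.approx(10.0, abs=1e-6)
        assert out["lateral_spine_mean"] == pytest.approx(0.0, abs=1e-6)

    def test_min_le_mean_le_max(self, noisy_walk):
        seq, _ = noisy_walk
        out = angle_based_parameters(seq)
        for sig in ("frontal_spine", "lateral_spine", "knee_left", "knee_right",
                    "hip_left", "hip_right"):
            assert out[f"{sig}_min"] <= out[f"{sig}_mean"] <= out[f"{sig}_max"]


class TestParameterVector:
    def test_angle_normalization_180_becomes_1_8(self):
        basic = {k: 0.0 for k in ("avg_step_length", "step_length_asymmetry",
                                  "step_width", "walking_speed")}
        phase = {k: 0.0 for k in ("stance_time_left", "stance_time_right",
                                  "swing_time_left", "swing_time_right")}
        angles = {f"{s}_{st}": 0.0 for s in (
            "frontal_spine", "lateral_spine", "knee_left", "knee_right",
            "hip_left", "hip_right") for st in ("mean", "min", "max")}
        angles["knee_left_max"] = 180.0
        vec = assemble_parameter_vector(basic, phase, angles)
        assert vec.as_dict()["knee_left_max"] == pytest.approx(1.8)

    def test_all_zero_inputs_zero_vector_of_26(self):
        zeros = {label: 0.0 for label in PARAMETER_LABELS}
        vec = assemble_parameter_vector(zeros, {}, {})
        assert vec.values.shape == (26,)
        np.testing.assert_array_equal(vec.values, 0.0)

    def test_full_walk_gives_26_labeled_entries(self, noisy_walk):
        seq, _ = noisy_walk
        vec = compute_parameter_vector(seq)
        assert vec.values.shape == (26,)
        assert vec.labels == PARAMETER_LABELS
        assert vec.labels[:4] == ("avg_step_length", "step_length_asymmetry",
                                  "step_width", "walking_speed")

    def test_non_finite_input_names_label(self):
        zeros = {label: 0.0 for label in PARAMETER_LABELS}
        zeros["step_width"] = float("nan")
        with pytest.raises(ValidationError, match="step_width"):
            assemble_parameter_vector(zeros, {}, {})

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            GaitParameterVector(np.zeros(7))


class TestMirrorInvariance:
    def test_mirroring_swaps_sides_and_preserves_symmetric_parameters(
            self, subject):
        style = style_for_class("antalgic", "left", scale=subject.step_scale)
        seq, _ = simulate_walk(style, subject, 300, 30.0, seed=6, noise_std=0.0)
        orig = compute_parameter_vector(seq).as_dict()
        mirr = compute_parameter_vector(mirror_sequence(seq)).as_dict()
        for key in ("step_length_asymmetry", "step_width", "walking_speed",
                    "avg_step_length"):
            assert mirr[key] == pytest.approx(orig[key], abs=1e-6)
        for key in ("stance_time_left", "swing_time_left", "knee_left_mean",
                    "hip_left_max"):
            other = key.replace("left", "right")
            assert mirr[key] == pytest.approx(orig[other], abs=1e-6)


class TestParameterRecovery:
    """Simulator outputs: commanded kinematics recovered within 5%."""

    @pytest.mark.parametrize("noise", [0.0, 0.005])
    @pytest.mark.parametrize("cls", ["normal", "antalgic", "steppage",
                                     "lurching", "stiff_legged",
                                     "trendelenburg"])
    def test_recovery_within_5_percent(self, cls, noise):
        for sid in (0, 1):
            subj = SubjectProfile.from_seed(f"R{sid}", 200 + sid)
            style = style_for_class(cls, "left" if sid else "right",
                                    scale=subj.step_scale)
            seq, gt = simulate_walk(style, subj, 600, 30.0, seed=20 + sid,
                                    noise_std=noise)
            ev = detect_gait_events(seq)
            basic = basic_parameters(seq, ev)
            phase = phase_parameters(ev, seq.fps)
            assert basic["walking_speed"] == pytest.approx(
                gt["walking_speed"], rel=0.05)
            commanded_avg = 0.5 * (gt["step_length_left"] +
                                   gt["step_length_right"])
            assert basic["avg_step_length"] == pytest.approx(
                commanded_avg, rel=0.05)
            for key in ("stance_time_left", "stance_time_right",
                        "swing_time_left", "swing_time_right"):
                assert phase[key] == pytest.approx(gt[key], rel=0.05), key
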