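"""Parametric kinematic simulator for normal and pathological walking.

Each walk is generated from piecewise-sinusoidal joint-angle templates over
normalized gait phase (heel strike at phase 0, toe off at the commanded
stance fraction) and turned into 3-D joint positions by forward kinematics
along the bone chains, so all bone lengths are conserved exactly in the
zero-noise case.  The hip-flexion amplitude of each leg is solved
numerically so the walk realizes the commanded per-side step lengths, and
ground-truth gait events plus commanded parameters are returned beside every
sequence.

Gait-class signatures (affected side chosen per subject):

* ``antalgic`` — shortened stance and shorter step on the affected side;
* ``steppage`` — exaggerated hip/knee flexion and foot drop in swing;
* ``lurching`` — posterior trunk-lean pulse around affected heel strike;
* ``stiff_legged`` — near-zero knee flexion on the affected side;
* ``trendelenburg`` — pelvic drop plus lateral trunk lean over affected stance;
* ``vestibular_like`` — slow, unstable walking with heading and timing noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, ValidationError
from .skeleton import (
    GaitDataset,
    GaitExample,
    JointSet,
    SkeletonSequence,
    default_joint_set,
    mirror_lr,
)

__all__ = [
    "GaitStyle",
    "SubjectProfile",
    "SimSpec",
    "GAIT_CLASSES",
    "style_for_class",
    "simulate_walk",
    "generate_dataset",
    "generate_vestibular_like",
]

GAIT_CLASSES = ("normal", "antalgic", "steppage", "lurching", "stiff_legged",
                "trendelenburg")

#: knee swing flexion timing exponent; > 1 keeps the ankle-forward signal
#: extremal exactly at heel strike / toe off
_KNEE_PHASE_EXP = 1.3
#: hip swing flexion added to every gait (radians)
_BASE_SWING_BOOST = 0.22
#: hip template shape exponent; > 1 sharpens the extrema of the
#: ankle-forward signal so coordinate-based event detection is well posed
_HIP_SHAPE_EXP = 2.0


@dataclass(frozen=True)
class GaitStyle:
    """Perturbation parameters defining one gait class realization."""

    name: str
    stance_frac: tuple[float, float] = (0.60, 0.60)      # (left, right)
    step_length: tuple[float, float] = (0.60, 0.60)      # meters
    knee_amp: tuple[float, float] = (0.80, 0.80)         # swing flexion, rad
    knee_stance: float = 0.10                            # stance flexion, rad
    hip_swing_boost: tuple[float, float] = (0.0, 0.0)    # extra swing hip, rad
    foot_drop: tuple[float, float] = (0.0, 0.0)          # swing toe-down, rad
    trunk_lateral_amp: float = 0.0                       # rad, toward stance side
    trunk_posterior_amp: float = 0.0                     # rad, at heel strike
    pelvic_drop_amp: float = 0.0                         # rad, contralateral drop
    lateral_sway_amp: float = 0.02                       # meters
    heading_noise: float = 0.0                           # m / sqrt(s)
    phase_jitter: float = 0.0                            # relative cycle noise
    affected: str = "left"

    def __post_init__(self) -> None:
        for f in self.stance_frac:
            if not 0.0 < f < 1.0:
                raise ValidationError("stance fraction must lie in (0, 1)")
        if min(self.step_length) <= 0:
            raise ValidationError("step lengths must be positive")
        if min(self.knee_amp) < 0 or min(self.hip_swing_boost) < 0:
            raise ValidationError("amplitudes must be nonnegative")
        if self.affected not in ("left", "right"):
            raise ValidationError("affected side must be 'left' or 'right'")


def _sided(base: float, affected_value: float, affected: str) -> tuple[float, float]:
    if affected == "left":
        return (affected_value, base)
    return (base, affected_value)


def style_for_class(name: str, affected: str = "left",
                    scale: float = 1.0) -> GaitStyle:
    """Default perturbation parameters for a gait class.

    ``scale`` multiplies the commanded step lengths (used for per-subject
    stature scaling).
    """
    s = scale
    base = dict(name=name, affected=affected,
                step_length=(0.60 * s, 0.60 * s))
    if name == "normal":
        return GaitStyle(**base)
    if name == "antalgic":
        return GaitStyle(**{**base,
                            "stance_frac": _sided(0.62, 0.46, affected),
                            "step_length": _sided(0.60 * s, 0.38 * s, affected)})
    if name == "steppage":
        return GaitStyle(**{**base,
                            "knee_amp": _sided(0.80, 1.25, affected),
                            "hip_swing_boost": _sided(0.0, 0.30, affected),
                            "foot_drop": _sided(0.0, 0.55, affected)})
    if name == "lurching":
        return GaitStyle(**{**base, "trunk_posterior_amp": 0.26})
    if name == "stiff_legged":
        return GaitStyle(**{**base,
                            "knee_amp": _sided(0.80, 0.06, affected),
                            "lateral_sway_amp": 0.035})
    if name == "trendelenburg":
        return GaitStyle(**{**base,
                            "pelvic_drop_amp": 0.16,
                            "trunk_lateral_amp": 0.22})
    if name == "vestibular_like":
        return GaitStyle(**{**base,
                            "step_length": (0.46 * s, 0.50 * s),
                            "lateral_sway_amp": 0.045,
                            "heading_noise": 0.035,
                            "phase_jitter": 0.05})
    raise ConfigurationError(f"unknown gait class {name!r}")


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometry and preferred timing for one simulated subject."""

    subject_id: str
    height: float
    cycle_s: float
    affected_side: str
    seed: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.cycle_s <= 0:
            raise ValidationError("height and cycle duration must be positive")

    @classmethod
    def from_seed(cls, subject_id: str, seed: int) -> "SubjectProfile":
        rng = np.random.default_rng(seed)
        return cls(
            subject_id=subject_id,
            height=float(rng.uniform(1.55, 1.85)),
            cycle_s=float(rng.uniform(0.86, 0.96)),
            affected_side="left" if rng.random() < 0.5 else "right",
            seed=seed,
        )

    # segment lengths as standard stature fractions
    @property
    def thigh(self) -> float:
        return 0.245 * self.height

    @property
    def shank(self) -> float:
        return 0.246 * self.height

    @property
    def foot_len(self) -> float:
        return 0.150 * self.height

    @property
    def trunk_len(self) -> float:
        return 0.470 * self.height

    @property
    def hip_width(self) -> float:
        return 0.180 * self.height

    @property
    def shoulder_width(self) -> float:
        return 0.230 * self.height

    @property
    def pelvis_height(self) -> float:
        return self.thigh + self.shank + 0.04

    @property
    def step_scale(self) -> float:
        return self.height / 1.70


@dataclass(frozen=True)
class SimSpec:
    """Dataset-level simulation specification."""

    n_subjects: int = 12
    n_walks: int = 20
    classes: tuple[str, ...] = GAIT_CLASSES
    frames_range: tuple[int, int] = (80, 120)
    fps: float = 30.0
    noise_std: float = 0.003
    seed: int = 0
    mirror_augment: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_walks < 1:
            raise ValidationError("subject and walk counts must be positive")
        lo, hi = self.frames_range
        if not 2 <= lo <= hi:
            raise ValidationError("invalid frames range")
        if self.fps <= 0 or self.noise_std < 0:
            raise ValidationError("fps must be positive and noise nonnegative")


# ---------------------------------------------------------------------------
# leg joint-angle templates over normalized phase
# ---------------------------------------------------------------------------

def _warp(phi: np.ndarray, sf: float) -> np.ndarray:
    """Map phase so stance covers [0, 0.5] and swing (0.5, 1) uniformly."""
    phi = np.mod(phi, 1.0)
    stance = phi < sf
    psi = np.where(stance, 0.5 * phi / sf, 0.5 + 0.5 * (phi - sf) / (1.0 - sf))
    return psi


def _swing_progress(phi: np.ndarray, sf: float) -> np.ndarray:
    phi = np.mod(phi, 1.0)
    u = np.clip((phi - sf) / (1.0 - sf), 0.0, 1.0)
    return np.where(phi >= sf, u, 0.0)


def _leg_angles(phi: np.ndarray, amp: float, sf: float, knee_amp: float,
                knee_stance: float, boost: float,
                foot_drop: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hip flexion, knee flexion, foot pitch) in radians for phase array."""
    phi = np.mod(phi, 1.0)
    psi = _warp(phi, sf)
    u = _swing_progress(phi, sf)
    swing = phi >= sf
    c = np.cos(2.0 * np.pi * psi)
    # sharpen the template during stance only: its cosine is much flatter at
    # the extrema than the swing side, which would make the coordinate-based
    # event extrema ill-conditioned under sensor noise
    shaped = np.sign(c) * np.abs(c) ** _HIP_SHAPE_EXP
    hip = amp * np.where(swing, c, shaped)
    hip = hip + (_BASE_SWING_BOOST + boost) * np.sin(np.pi * u) ** 2
    knee = np.where(swing,
                    knee_amp * np.sin(np.pi * u ** _KNEE_PHASE_EXP) ** 2,
                    knee_stance * np.sin(np.pi * phi / sf) ** 2)
    foot = np.where(swing, foot_drop * np.sin(np.pi * u) ** 2, 0.0)
    return hip, knee, foot


def _ankle_forward(phi: float, amp: float, sf: float, knee_amp: float,
                   knee_stance: float, boost: float,
                   thigh: float, shank: float) -> float:
    """Forward ankle offset relative to the hip at one phase value."""
    hip, knee, _ = _leg_angles(np.array([phi]), amp, sf, knee_amp, knee_stance,
                               boost, 0.0)
    return float(thigh * np.sin(hip[0]) + shank * np.sin(hip[0] - knee[0]))


def _solve_walk_timing(style: GaitStyle, subject: SubjectProfile
                       ) -> tuple[float, float, dict[str, float]]:
    """Solve the hip amplitude and inter-leg phase offset for the step plan.

    A common hip-flexion amplitude sets the stride length; step-length
    asymmetry is realized by shifting the right leg's phase offset away from
    half a cycle (timing asymmetry, as in antalgic walking).  Returns
    ``(amplitude, offset, realized step lengths)``; when the commanded
    asymmetry exceeds what the kinematics can express the offset saturates
    and the realized (analytic) step lengths are reported instead.
    """
    sides = ("left", "right")
    sf = dict(zip(sides, style.stance_frac))
    kamp = dict(zip(sides, style.knee_amp))
    boost = dict(zip(sides, style.hip_swing_boost))
    t_left, t_right = style.step_length

    def z(side: str, phi: float, a: float) -> float:
        return _ankle_forward(phi % 1.0, a, sf[side], kamp[side],
                              style.knee_stance, boost[side],
                              subject.thigh, subject.shank)

    def steps(a: float, d: float) -> tuple[float, float]:
        s_left = z("left", 0.0, a) - z("right", d, a)
        s_right = z("right", 0.0, a) - z("left", 1.0 - d, a)
        return s_left, s_right

    def solve_amp(d: float) -> float:
        return brentq(lambda a: sum(steps(a, d)) - (t_left + t_right),
                      1e-4, 1.35, xtol=1e-12)

    def asym_gap(d: float) -> float:
        s_left, s_right = steps(solve_amp(d), d)
        return (s_left - s_right) - (t_left - t_right)

    lo, hi = 0.32, 0.68
    try:
        delta = brentq(asym_gap, lo, hi, xtol=1e-10)
    except ValueError:
        delta = lo if abs(asym_gap(lo)) < abs(asym_gap(hi)) else hi
    amp = solve_amp(delta)
    s_left, s_right = steps(amp, delta)
    return amp, delta, {"left": s_left, "right": s_right}


def _rot_x(a: np.ndarray) -> np.ndarray:
    """Stack of rotations about the lateral axis, shape (T, 3, 3)."""
    c, s = np.cos(a), np.sin(a)
    T = len(a)
    R = np.zeros((T, 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1], R[:, 1, 2] = c, -s
    R[:, 2, 1], R[:, 2, 2] = s, c
    return R


def _rot_z(a: np.ndarray) -> np.ndarray:
    """Stack of rotations about the forward axis, shape (T, 3, 3)."""
    c, s = np.cos(a), np.sin(a)
    T = len(a)
    R = np.zeros((T, 3, 3))
    R[:, 2, 2] = 1.0
    R[:, 0, 0], R[:, 0, 1] = c, -s
    R[:, 1, 0], R[:, 1, 1] = s, c
    return R


def _bump(phi: np.ndarray, sf: float) -> np.ndarray:
    """Unit bump over the stance interval, zero in swing."""
    phi = np.mod(phi, 1.0)
    return np.where(phi < sf, np.sin(np.pi * phi / sf) ** 2, 0.0)


def _phase_crossings(total_phase: np.ndarray, offset: float,
                     fps: float) -> list[int]:
    """Nearest frame indices where the unwrapped phase crosses k + offset."""
    lo = int(np.ceil(total_phase[0] - offset))
    hi = int(np.floor(total_phase[-1] - offset))
    frames = []
    for k in range(lo, hi + 1):
        target = k + offset
        idx = int(np.searchsorted(total_phase, target))
        if idx == 0:
            frame = 0
        else:
            t0, t1 = total_phase[idx - 1], total_phase[idx]
            frac = 0.0 if t1 == t0 else (target - t0) / (t1 - t0)
            frame = int(round(idx - 1 + frac))
        if 0 <= frame < len(total_phase) and (not frames or frame > frames[-1]):
            frames.append(frame)
    return frames


def simulate_walk(
    style: GaitStyle,
    subject: SubjectProfile,
    n_frames: int,
    fps: float = 30.0,
    seed: int = 0,
    noise_std: float = 0.003,
    joints: JointSet | None = None,
) -> tuple[SkeletonSequence, dict]:
    """Simulate one walk; returns the sequence and its ground truth.

    The ground-truth dict holds the event frame lists
    (``heel_strikes_left/right``, ``toe_offs_left/right``) and the commanded
    parameters (step lengths, walking speed, stance/swing times, cycle
    duration), all keyed flat so left/right entries swap under mirroring.
    """
    if n_frames < 2:
        raise ValidationError("need at least two frames")
    joints = joints if joints is not None else default_joint_set()
    rng = np.random.default_rng(seed)
    sides = ("left", "right")
    sf = dict(zip(sides, style.stance_frac))
    kamp = dict(zip(sides, style.knee_amp))
    boost = dict(zip(sides, style.hip_swing_boost))
    fdrop = dict(zip(sides, style.foot_drop))
    amp_val, delta, realized_steps = _solve_walk_timing(style, subject)
    amp = {"left": amp_val, "right": amp_val}

    dt = 1.0 / fps
    t = np.arange(n_frames) * dt
    cycle = subject.cycle_s
    speed = sum(style.step_length) / cycle

    phi0 = float(rng.uniform(0.0, 1.0))
    dphi = np.full(n_frames, dt / cycle)
    if style.phase_jitter > 0:
        dphi *= 1.0 + style.phase_jitter * rng.standard_normal(n_frames)
    total_left = phi0 + np.concatenate([[0.0], np.cumsum(dphi[1:])])
    total = {"left": total_left, "right": total_left + delta}
    phi = {s: np.mod(total[s], 1.0) for s in sides}
    phi_aff = phi[style.affected]
    sf_aff = sf[style.affected]

    # pelvis trajectory
    pelvis = np.zeros((n_frames, 3))
    pelvis[:, 2] = speed * t
    pelvis[:, 1] = subject.pelvis_height + 0.015 * np.cos(
        4.0 * np.pi * phi["left"])
    sway_sign = 1.0  # toward the stance-side leg
    pelvis[:, 0] = style.lateral_sway_amp * sway_sign * np.sin(
        2.0 * np.pi * (phi["left"] - 0.3))
    if style.heading_noise > 0:
        drift = np.cumsum(rng.normal(0.0, style.heading_noise * np.sqrt(dt),
                                     n_frames))
        pelvis[:, 0] += drift

    # pelvic roll: positive roll raises the left hip / drops the right hip
    roll_sign = 1.0 if style.affected == "left" else -1.0
    roll = roll_sign * style.pelvic_drop_amp * _bump(phi_aff, sf_aff)
    R_roll = _rot_z(roll)

    # trunk orientation: lateral lean toward the affected stance side,
    # posterior lean pulse centered on affected heel strike
    lean_lat_sign = -1.0 if style.affected == "left" else 1.0
    lean_lat = lean_lat_sign * style.trunk_lateral_amp * _bump(phi_aff, sf_aff)
    strike_pulse = (0.5 * (1.0 + np.cos(2.0 * np.pi * phi_aff))) ** 2
    lean_post = -style.trunk_posterior_amp * strike_pulse
    R_trunk = np.einsum("tij,tjk->tik", _rot_z(lean_lat), _rot_x(lean_post))

    pos = {name: np.zeros((n_frames, 3)) for name in joints.names}
    pos["pelvis"] = pelvis

    # upper body: fixed local offsets rotated by the trunk orientation
    tl = subject.trunk_len
    locals_up = {
        "spine_navel": np.array([0.0, 0.27 * tl, 0.0]),
        "spine_chest": np.array([0.0, 0.55 * tl, 0.0]),
        "neck": np.array([0.0, 0.82 * tl, 0.0]),
        "head": np.array([0.0, tl, 0.0]),
    }
    sw = subject.shoulder_width
    arm_upper, arm_fore = 0.172 * subject.height, 0.157 * subject.height
    arm_amp = 0.35 * amp_val
    for s, sign, opp in (("left", 1.0, "right"), ("right", -1.0, "left")):
        theta_a = arm_amp * np.cos(2.0 * np.pi * _warp(phi[opp], sf[opp]))
        shoulder = np.array([sign * sw / 2.0, 0.75 * tl, 0.0])
        elbow = shoulder + arm_upper * np.stack(
            [np.zeros(n_frames), -np.cos(theta_a), np.sin(theta_a)], axis=1)
        wrist = elbow + arm_fore * np.stack(
            [np.zeros(n_frames), -np.cos(theta_a + 0.35),
             np.sin(theta_a + 0.35)], axis=1)
        locals_up[f"shoulder_{s}"] = shoulder
        pos[f"elbow_{s}"] = pelvis + np.einsum("tij,tj->ti", R_trunk, elbow)
        pos[f"wrist_{s}"] = pelvis + np.einsum("tij,tj->ti", R_trunk, wrist)
    for name, local in locals_up.items():
        local_t = np.broadcast_to(local, (n_frames, 3))
        pos[name] = pelvis + np.einsum("tij,tj->ti", R_trunk, local_t)

    # legs: hip offsets rotated by pelvic roll, then planar forward kinematics
    for s, sign in (("left", 1.0), ("right", -1.0)):
        hip_off = np.broadcast_to(
            np.array([sign * subject.hip_width / 2.0, -0.03, 0.0]),
            (n_frames, 3))
        hip_pos = pelvis + np.einsum("tij,tj->ti", R_roll, hip_off)
        hip_ang, knee_ang, foot_ang = _leg_angles(
            phi[s], amp[s], sf[s], kamp[s], style.knee_stance, boost[s],
            fdrop[s])
        thigh_dir = np.stack([np.zeros(n_frames), -np.cos(hip_ang),
                              np.sin(hip_ang)], axis=1)
        knee_pos = hip_pos + subject.thigh * thigh_dir
        shank_ang = hip_ang - knee_ang
        shank_dir = np.stack([np.zeros(n_frames), -np.cos(shank_ang),
                              np.sin(shank_ang)], axis=1)
        ankle_pos = knee_pos + subject.shank * shank_dir
        foot_dir = np.stack([np.zeros(n_frames), -np.sin(foot_ang),
                             np.cos(foot_ang)], axis=1)
        foot_pos = ankle_pos + subject.foot_len * foot_dir
        pos[f"hip_{s}"] = hip_pos
        pos[f"knee_{s}"] = knee_pos
        pos[f"ankle_{s}"] = ankle_pos
        pos[f"foot_{s}"] = foot_pos

    positions = np.stack([pos[name] for name in joints.names], axis=1)
    if noise_std > 0:
        positions = positions + rng.normal(0.0, noise_std, positions.shape)
    seq = SkeletonSequence(joints, positions, fps)

    ground_truth: dict = {
        "cycle_s": cycle,
        "walking_speed": speed,
    }
    for s in sides:
        ground_truth[f"step_length_{s}"] = realized_steps[s]
        ground_truth[f"stance_time_{s}"] = sf[s] * cycle
        ground_truth[f"swing_time_{s}"] = (1.0 - sf[s]) * cycle
        ground_truth[f"heel_strikes_{s}"] = _phase_crossings(total[s], 0.0, fps)
        ground_truth[f"toe_offs_{s}"] = _phase_crossings(total[s], sf[s], fps)
    n_cycles = n_frames * dt / cycle
    if n_cycles < 2.0:
        ground_truth["warning"] = (
            f"only {n_cycles:.2f} gait cycles simulated (< 2)")
    return seq, ground_truth


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _subject_profiles(n: int, seed_seq: np.random.SeedSequence,
                      prefix: str = "S") -> list[SubjectProfile]:
    children = seed_seq.spawn(n)
    return [
        SubjectProfile.from_seed(f"{prefix}{i:03d}",
                                 int(child.generate_state(1)[0]))
        for i, child in enumerate(children)
    ]


def generate_dataset(spec: SimSpec) -> GaitDataset:
    """Simulate ``n_subjects x |classes| x n_walks`` labeled walks.

    With ``mirror_augment`` every example is additionally present
    left/right-mirrored (same subject id, mirrored flag set), doubling the
    example count.
    """
    root = np.random.SeedSequence(spec.seed)
    subj_ss, walk_ss = root.spawn(2)
    subjects = _subject_profiles(spec.n_subjects, subj_ss)
    walk_rng = np.random.default_rng(walk_ss)
    examples: list[GaitExample] = []
    for subject in subjects:
        for label, class_name in enumerate(spec.classes):
            style = style_for_class(class_name, subject.affected_side,
                                    scale=subject.step_scale)
            for walk in range(spec.n_walks):
                n_frames = int(walk_rng.integers(spec.frames_range[0],
                                                 spec.frames_range[1] + 1))
                walk_seed = int(walk_rng.integers(0, 2**63 - 1))
                seq, gt = simulate_walk(style, subject, n_frames, spec.fps,
                                        seed=walk_seed,
                                        noise_std=spec.noise_std)
                examples.append(GaitExample(
                    sequence=seq, subject_id=subject.subject_id,
                    gait_label=label, walk_index=walk, ground_truth=gt))
    if spec.mirror_augment:
        examples = examples + [mirror_lr(ex) for ex in examples]
    return GaitDataset(
        examples=examples,
        class_names=tuple(spec.classes),
        provenance={
            "generator": "gaitrec.synth.generate_dataset",
            "n_subjects": spec.n_subjects,
            "n_walks": spec.n_walks,
            "seed": spec.seed,
            "mirror_augment": spec.mirror_augment,
        },
    )


def generate_vestibular_like(
    n_subjects: int = 161,
    n_walks: int = 2,
    n_short: int = 10,
    healthy_fraction: float = 33.0 / 161.0,
    frames_range: tuple[int, int] = (95, 120),
    short_frames_range: tuple[int, int] = (75, 89),
    fps: float = 30.0,
    noise_std: float = 0.003,
    seed: int = 0,
) -> GaitDataset:
    """Binary healthy-vs-disorder dataset with a few deliberately short walks.

    ``n_short`` examples (chosen deterministically from the seed) receive a
    sequence shorter than 90 frames so that minimum-length filtering can be
    exercised; labels are 0 (healthy) or 1 (vestibular-like disorder).
    """
    total = n_subjects * n_walks
    if n_short > total:
        raise ValidationError("n_short exceeds the number of examples")
    root = np.random.SeedSequence(seed)
    subj_ss, walk_ss, short_ss = root.spawn(3)
    subjects = _subject_profiles(n_subjects, subj_ss, prefix="V")
    n_healthy = int(round(healthy_fraction * n_subjects))
    short_rng = np.random.default_rng(short_ss)
    short_slots = set(short_rng.choice(total, size=n_short, replace=False).tolist())
    walk_rng = np.random.default_rng(walk_ss)
    examples: list[GaitExample] = []
    slot = 0
    for i, subject in enumerate(subjects):
        label = 0 if i < n_healthy else 1
        class_name = "normal" if label == 0 else "vestibular_like"
        style = style_for_class(class_name, subject.affected_side,
                                scale=subject.step_scale)
        for walk in range(n_walks):
            rng_lo, rng_hi = (short_frames_range if slot in short_slots
                              else frames_range)
            n_frames = int(walk_rng.integers(rng_lo, rng_hi + 1))
            walk_seed = int(walk_rng.integers(0, 2**63 - 1))
            seq, gt = simulate_walk(style, subject, n_frames, fps,
                                    seed=walk_seed, noise_std=noise_std)
            examples.append(GaitExample(
                sequence=seq, subject_id=subject.subject_id, gait_label=label,
                walk_index=walk, ground_truth=gt))
            slot += 1
    return GaitDataset(
        examples=examples,
        class_names=("healthy", "vestibular_disorder"),
        provenance={
            "generator": "gaitrec.synth.generate_vestibular_like",
            "n_subjects": n_subjects,
            "n_walks": n_walks,
            "n_short": n_short,
            "seed": seed,
        },
    )
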