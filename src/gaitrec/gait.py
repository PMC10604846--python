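"""Gait event detection and gait-parameter extraction.

Heel strikes and toe offs are detected as the local maxima / minima of each
ankle's forward displacement relative to the pelvis (coordinate-based method).
From the events and the skeleton sequence three parameter families are
computed:

* basic: average step length, step length asymmetry, step width, walking speed;
* phase-based: stance and swing times for each leg (seconds);
* angle-based: mean/min/max of the frontal spine, lateral spine, and left and
  right knee and hip angle signals.

The families are assembled into a fixed 26-entry vector whose angle-derived
entries are divided by 100 so that all entries share a comparable 0-2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .angles import BendingAngleDef, bending_angle
from .errors import InsufficientGaitCyclesError, ValidationError
from .skeleton import (
    FORWARD_AXIS,
    LATERAL_AXIS,
    VERTICAL_AXIS,
    SkeletonSequence,
)

__all__ = [
    "GaitEvents",
    "GaitParameterVector",
    "PARAMETER_LABELS",
    "detect_gait_events",
    "basic_parameters",
    "phase_parameters",
    "angle_based_parameters",
    "assemble_parameter_vector",
    "compute_parameter_vector",
]

#: minimum temporal separation between same-kind events, seconds
MIN_EVENT_SEPARATION_S = 0.4
#: minimum peak prominence (meters) for event detection; genuine gait events
#: swing the ankle-minus-pelvis signal by tens of centimeters
EVENT_PROMINENCE_M = 0.03

_ANGLE_SIGNALS = ("frontal_spine", "lateral_spine", "knee_left", "knee_right",
                  "hip_left", "hip_right")

PARAMETER_LABELS: tuple[str, ...] = (
    "avg_step_length",
    "step_length_asymmetry",
    "step_width",
    "walking_speed",
    "stance_time_left",
    "stance_time_right",
    "swing_time_left",
    "swing_time_right",
) + tuple(
    f"{sig}_{stat}" for sig in _ANGLE_SIGNALS for stat in ("mean", "min", "max")
)


def _check_events(frames: list[int], kind: str, side: str) -> None:
    if any(b <= a for a, b in zip(frames, frames[1:])):
        raise ValidationError(f"{kind} frames for {side} side not strictly increasing")


@dataclass
class GaitEvents:
    """Frame indices of heel strikes and toe offs per side."""

    heel_strikes_left: list[int]
    heel_strikes_right: list[int]
    toe_offs_left: list[int]
    toe_offs_right: list[int]

    def __post_init__(self) -> None:
        _check_events(self.heel_strikes_left, "heel strike", "left")
        _check_events(self.heel_strikes_right, "heel strike", "right")
        _check_events(self.toe_offs_left, "toe off", "left")
        _check_events(self.toe_offs_right, "toe off", "right")

    def strikes(self, side: str) -> list[int]:
        return self.heel_strikes_left if side == "left" else self.heel_strikes_right

    def toe_offs(self, side: str) -> list[int]:
        return self.toe_offs_left if side == "left" else self.toe_offs_right


@dataclass
class GaitParameterVector:
    """Fixed-length normalized gait parameter vector (default 26 entries)."""

    values: np.ndarray
    labels: tuple[str, ...] = PARAMETER_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.labels),):
            raise ValidationError(
                f"expected {len(self.labels)} values, got {self.values.shape}"
            )
        bad = np.argwhere(~np.isfinite(self.values)).ravel()
        if bad.size:
            raise ValidationError(f"non-finite parameter {self.labels[bad[0]]!r}")

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.labels, self.values)}


def _refine_peaks(signal: np.ndarray, peaks: np.ndarray) -> list[int]:
    """Sub-frame parabolic peak refinement, rounded back to frame indices.

    Removes the systematic lean of the discrete argmax onto the flatter side
    of an asymmetric extremum.
    """
    refined: list[int] = []
    for p in peaks:
        frame = int(p)
        if 1 <= p < len(signal) - 1:
            y0, y1, y2 = signal[p - 1], signal[p], signal[p + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < -1e-15:
                offset = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
                frame = int(round(p + offset))
        if not refined or frame > refined[-1]:
            refined.append(frame)
    return refined


def detect_gait_events(
    seq: SkeletonSequence,
    min_separation_s: float = MIN_EVENT_SEPARATION_S,
    prominence_m: float = EVENT_PROMINENCE_M,
) -> GaitEvents:
    """Detect heel strikes / toe offs from ankle-minus-pelvis forward motion.

    Heel strike = local maximum of the ankle's forward displacement relative
    to the pelvis; toe off = local minimum of the same signal.  Requires at
    least two detected strikes per side.
    """
    pelvis_z = seq.joint_trajectory("pelvis")[:, FORWARD_AXIS]
    distance = max(1, int(round(min_separation_s * seq.fps)))
    out: dict[str, list[int]] = {}
    for side in ("left", "right"):
        signal = seq.joint_trajectory(f"ankle_{side}")[:, FORWARD_AXIS] - pelvis_z
        strikes, _ = find_peaks(signal, distance=distance, prominence=prominence_m)
        offs, _ = find_peaks(-signal, distance=distance, prominence=prominence_m)
        strikes = _refine_peaks(signal, strikes)
        offs = _refine_peaks(-signal, offs)
        if len(strikes) < 2:
            raise InsufficientGaitCyclesError(
                f"insufficient gait cycles: {len(strikes)} heel strikes "
                f"detected on the {side} side (need >= 2)"
            )
        out[f"strikes_{side}"] = [int(i) for i in strikes]
        out[f"offs_{side}"] = [int(i) for i in offs]
    return GaitEvents(
        heel_strikes_left=out["strikes_left"],
        heel_strikes_right=out["strikes_right"],
        toe_offs_left=out["offs_left"],
        toe_offs_right=out["offs_right"],
    )


def basic_parameters(seq: SkeletonSequence, ev: GaitEvents) -> dict[str, float]:
    """Average step length, step length asymmetry, step width, walking speed."""
    ankle = {s: seq.joint_trajectory(f"ankle_{s}") for s in ("left", "right")}
    step_lengths: dict[str, list[float]] = {"left": [], "right": []}
    widths: list[float] = []
    for side, other in (("left", "right"), ("right", "left")):
        for f in ev.strikes(side):
            lead = ankle[side][f, FORWARD_AXIS]
            trail = ankle[other][f, FORWARD_AXIS]
            step_lengths[side].append(abs(float(lead - trail)))
            widths.append(abs(float(
                ankle["left"][f, LATERAL_AXIS] - ankle["right"][f, LATERAL_AXIS]
            )))
    mean_l = float(np.mean(step_lengths["left"]))
    mean_r = float(np.mean(step_lengths["right"]))
    avg_step = float(np.mean(step_lengths["left"] + step_lengths["right"]))
    denom = mean_l + mean_r
    asymmetry = 0.0 if denom == 0 else 2.0 * abs(mean_l - mean_r) / denom
    elapsed = seq.duration
    if elapsed <= 0:
        raise ValidationError("zero elapsed time; cannot compute walking speed")
    pelvis_z = seq.joint_trajectory("pelvis")[:, FORWARD_AXIS]
    speed = float(abs(pelvis_z[-1] - pelvis_z[0]) / elapsed)
    return {
        "avg_step_length": avg_step,
        "step_length_asymmetry": asymmetry,
        "step_width": float(np.mean(widths)),
        "walking_speed": speed,
    }


def _mean_interval(
    starts: list[int], ends: list[int], fps: float, what: str
) -> float:
    """Mean duration (s) from each start event to the next end event."""
    durations = []
    for s in starts:
        nxt = [e for e in ends if e > s]
        if nxt:
            durations.append((nxt[0] - s) / fps)
    if not durations:
        raise ValidationError(f"no complete {what} intervals found")
    return float(np.mean(durations))


def phase_parameters(ev: GaitEvents, fps: float) -> dict[str, float]:
    """Per-side mean stance and swing times in seconds.

    Stance = heel strike to the next toe off; swing = toe off to the next
    heel strike.  Events on each side must alternate.
    """
    if fps <= 0:
        raise ValidationError("fps must be positive")
    out: dict[str, float] = {}
    for side in ("left", "right"):
        strikes, offs = ev.strikes(side), ev.toe_offs(side)
        merged = sorted(
            [(f, "strike") for f in strikes] + [(f, "off") for f in offs]
        )
        for (f0, k0), (f1, k1) in zip(merged, merged[1:]):
            if k0 == k1:
                raise ValidationError(
                    f"non-alternating gait events on the {side} side "
                    f"(consecutive {k0}s at frames {f0} and {f1})"
                )
        out[f"stance_time_{side}"] = _mean_interval(strikes, offs, fps, "stance")
        out[f"swing_time_{side}"] = _mean_interval(offs, strikes, fps, "swing")
    return out


def _spine_angles(seq: SkeletonSequence) -> tuple[np.ndarray, np.ndarray]:
    """Frontal and lateral spine angle signals in degrees.

    The trunk vector (pelvis -> head) is projected onto the frontal
    (lateral-vertical) and sagittal (forward-vertical) planes; each angle is
    the unsigned deviation of the projection from the vertical axis.
    """
    trunk = seq.joint_trajectory("head") - seq.joint_trajectory("pelvis")
    norms = np.linalg.norm(trunk, axis=1)
    if (norms < 1e-8).any():
        raise ValidationError("degenerate trunk vector")
    frontal = np.degrees(np.arctan2(
        np.abs(trunk[:, LATERAL_AXIS]), trunk[:, VERTICAL_AXIS]
    ))
    lateral = np.degrees(np.arctan2(
        np.abs(trunk[:, FORWARD_AXIS]), trunk[:, VERTICAL_AXIS]
    ))
    return frontal, lateral


def angle_based_parameters(seq: SkeletonSequence) -> dict[str, float]:
    """Mean/min/max of spine and knee/hip angle signals, in degrees."""
    frontal, lateral = _spine_angles(seq)
    signals = {"frontal_spine": frontal, "lateral_spine": lateral}
    for side in ("left", "right"):
        signals[f"knee_{side}"] = bending_angle(
            seq, BendingAngleDef(f"knee_{side}", f"hip_{side}", f"ankle_{side}")
        )
        signals[f"hip_{side}"] = bending_angle(
            seq, BendingAngleDef(f"hip_{side}", "pelvis", f"knee_{side}")
        )
    out: dict[str, float] = {}
    for name in _ANGLE_SIGNALS:
        sig = signals[name]
        out[f"{name}_mean"] = float(np.mean(sig))
        out[f"{name}_min"] = float(np.min(sig))
        out[f"{name}_max"] = float(np.max(sig))
    return out


def assemble_parameter_vector(
    basic: dict[str, float],
    phase: dict[str, float],
    angle_params: dict[str, float],
) -> GaitParameterVector:
    """Assemble the 26-entry vector; angle-derived entries are divided by 100."""
    merged = {**basic, **phase, **angle_params}
    values = []
    for label in PARAMETER_LABELS:
        if label not in merged:
            raise ValidationError(f"missing parameter {label!r}")
        v = float(merged[label])
        if not np.isfinite(v):
            raise ValidationError(f"non-finite parameter {label!r}")
        if any(label.startswith(sig) for sig in _ANGLE_SIGNALS):
            v /= 100.0
        values.append(v)
    return GaitParameterVector(np.array(values))


def compute_parameter_vector(seq: SkeletonSequence) -> GaitParameterVector:
    """End-to-end convenience: events -> parameter families -> vector."""
    ev = detect_gait_events(seq)
    return assemble_parameter_vector(
        basic_parameters(seq, ev),
        phase_parameters(ev, seq.fps),
        angle_based_parameters(seq),
    )
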