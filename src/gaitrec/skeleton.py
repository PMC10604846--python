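"""Skeleton sequence data model, file I/O, calibration and augmentation.

Coordinate convention (used throughout the package): right-handed frame with
``x`` = lateral, ``y`` = vertical (up), ``z`` = walking (forward) direction,
all positions in meters.  Frames are indexed from zero and windows are
half-open intervals.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import SkeletonFormatError, ValidationError

__all__ = [
    "JointSet",
    "SkeletonSequence",
    "RigidTransform",
    "GaitExample",
    "GaitDataset",
    "default_joint_set",
    "azure_kinect_joint_set",
    "load_skeleton_sequence",
    "save_skeleton_sequence",
    "apply_calibration",
    "mirror_sequence",
    "mirror_lr",
    "window_sequence",
    "filter_short_sequences",
    "save_dataset",
    "load_dataset",
]

log = logging.getLogger(__name__)

#: semantic roles every joint set must resolve
REQUIRED_ROLES = (
    "pelvis",
    "head",
    "hip_left",
    "hip_right",
    "knee_left",
    "knee_right",
    "ankle_left",
    "ankle_right",
    "foot_left",
    "foot_right",
)

LATERAL_AXIS = 0
VERTICAL_AXIS = 1
FORWARD_AXIS = 2


def _mirror_name(name: str) -> str | None:
    """Return the opposite-side joint name, or ``None`` for a central joint."""
    if "left" in name:
        return name.replace("left", "right")
    if "right" in name:
        return name.replace("right", "left")
    return None


@dataclass(frozen=True)
class JointSet:
    """An ordered, named joint set with semantic role mapping and bone list."""

    names: tuple[str, ...]
    roles: Mapping[str, str]
    bones: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("joint names must be unique")
        missing = [r for r in REQUIRED_ROLES if r not in self.roles]
        if missing:
            raise ValidationError(f"missing required roles: {missing}")
        for role, name in self.roles.items():
            if name not in self.names:
                raise ValidationError(f"role {role!r} maps to unknown joint {name!r}")
        for a, b in self.bones:
            if a not in self.names or b not in self.names:
                raise ValidationError(f"bone ({a!r}, {b!r}) references unknown joint")

    @property
    def n_joints(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown joint name {name!r}") from None

    def role_name(self, role_or_name: str) -> str:
        """Resolve a semantic role (or a literal joint name) to a joint name."""
        if role_or_name in self.roles:
            return self.roles[role_or_name]
        if role_or_name in self.names:
            return role_or_name
        raise ValidationError(f"unknown joint or role {role_or_name!r}")

    def role_index(self, role_or_name: str) -> int:
        return self.index(self.role_name(role_or_name))

    def lr_pairs(self) -> list[tuple[str, str]]:
        """Left/right joint name pairs; raises if a lateral joint is unpaired."""
        pairs: list[tuple[str, str]] = []
        for name in self.names:
            if "left" in name:
                other = _mirror_name(name)
                if other not in self.names:
                    raise ValidationError(f"unpaired lateral joint {name!r}")
                pairs.append((name, other))
            elif "right" in name and _mirror_name(name) not in self.names:
                raise ValidationError(f"unpaired lateral joint {name!r}")
        return pairs

    def bone_indices(self) -> list[tuple[int, int]]:
        return [(self.index(a), self.index(b)) for a, b in self.bones]


def default_joint_set() -> JointSet:
    """Bundled 19-joint subset of the Azure-Kinect-style skeleton."""
    names = (
        "pelvis",
        "spine_navel",
        "spine_chest",
        "neck",
        "head",
        "shoulder_left",
        "elbow_left",
        "wrist_left",
        "shoulder_right",
        "elbow_right",
        "wrist_right",
        "hip_left",
        "knee_left",
        "ankle_left",
        "foot_left",
        "hip_right",
        "knee_right",
        "ankle_right",
        "foot_right",
    )
    bones = (
        ("pelvis", "spine_navel"),
        ("spine_navel", "spine_chest"),
        ("spine_chest", "neck"),
        ("neck", "head"),
        ("spine_chest", "shoulder_left"),
        ("shoulder_left", "elbow_left"),
        ("elbow_left", "wrist_left"),
        ("spine_chest", "shoulder_right"),
        ("shoulder_right", "elbow_right"),
        ("elbow_right", "wrist_right"),
        ("pelvis", "hip_left"),
        ("hip_left", "knee_left"),
        ("knee_left", "ankle_left"),
        ("ankle_left", "foot_left"),
        ("pelvis", "hip_right"),
        ("hip_right", "knee_right"),
        ("knee_right", "ankle_right"),
        ("ankle_right", "foot_right"),
    )
    roles = {r: r for r in REQUIRED_ROLES}
    return JointSet(names=names, roles=roles, bones=bones)


def azure_kinect_joint_set() -> JointSet:
    """Full 32-joint Azure Kinect body-tracking skeleton (opt-in)."""
    names = (
        "pelvis", "spine_navel", "spine_chest", "neck",
        "clavicle_left", "shoulder_left", "elbow_left", "wrist_left",
        "hand_left", "handtip_left", "thumb_left",
        "clavicle_right", "shoulder_right", "elbow_right", "wrist_right",
        "hand_right", "handtip_right", "thumb_right",
        "hip_left", "knee_left", "ankle_left", "foot_left",
        "hip_right", "knee_right", "ankle_right", "foot_right",
        "head", "nose", "eye_left", "ear_left", "eye_right", "ear_right",
    )
    bones = (
        ("pelvis", "spine_navel"), ("spine_navel", "spine_chest"),
        ("spine_chest", "neck"), ("neck", "head"),
        ("head", "nose"), ("nose", "eye_left"), ("eye_left", "ear_left"),
        ("nose", "eye_right"), ("eye_right", "ear_right"),
        ("spine_chest", "clavicle_left"), ("clavicle_left", "shoulder_left"),
        ("shoulder_left", "elbow_left"), ("elbow_left", "wrist_left"),
        ("wrist_left", "hand_left"), ("hand_left", "handtip_left"),
        ("wrist_left", "thumb_left"),
        ("spine_chest", "clavicle_right"), ("clavicle_right", "shoulder_right"),
        ("shoulder_right", "elbow_right"), ("elbow_right", "wrist_right"),
        ("wrist_right", "hand_right"), ("hand_right", "handtip_right"),
        ("wrist_right", "thumb_right"),
        ("pelvis", "hip_left"), ("hip_left", "knee_left"),
        ("knee_left", "ankle_left"), ("ankle_left", "foot_left"),
        ("pelvis", "hip_right"), ("hip_right", "knee_right"),
        ("knee_right", "ankle_right"), ("ankle_right", "foot_right"),
    )
    roles = {r: r for r in REQUIRED_ROLES}
    return JointSet(names=names, roles=roles, bones=bones)


@dataclass
class SkeletonSequence:
    """A ``T x N x 3`` sequence of 3-D joint positions in meters."""

    joints: JointSet
    positions: np.ndarray
    fps: float = 30.0
    frame_timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError(
                f"positions must be T x N x 3, got {self.positions.shape}"
            )
        if self.positions.shape[0] < 1:
            raise ValidationError("sequence must contain at least one frame")
        if self.positions.shape[1] != self.joints.n_joints:
            raise ValidationError(
                f"positions have {self.positions.shape[1]} joints, "
                f"joint set has {self.joints.n_joints}"
            )
        if not np.isfinite(self.positions).all():
            t, n, _ = np.argwhere(~np.isfinite(self.positions))[0]
            raise ValidationError(
                f"non-finite coordinate at frame {t}, joint {self.joints.names[n]!r}"
            )
        if not self.fps > 0:
            raise ValidationError("fps must be positive")
        if self.frame_timestamps is not None:
            self.frame_timestamps = np.asarray(self.frame_timestamps, dtype=np.float64)
            if self.frame_timestamps.shape != (self.positions.shape[0],):
                raise ValidationError("frame_timestamps length must equal T")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Elapsed time of the sequence in seconds."""
        if self.frame_timestamps is not None:
            return float(self.frame_timestamps[-1] - self.frame_timestamps[0])
        return (self.n_frames - 1) / self.fps

    def joint_trajectory(self, role_or_name: str) -> np.ndarray:
        """``T x 3`` trajectory of one joint, addressed by role or name."""
        return self.positions[:, self.joints.role_index(role_or_name), :]

    def copy(self) -> "SkeletonSequence":
        ts = None if self.frame_timestamps is None else self.frame_timestamps.copy()
        return SkeletonSequence(self.joints, self.positions.copy(), self.fps, ts)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64)
        )
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length-3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an array of points with trailing dimension 3."""
        return points @ self.rotation.T + self.translation


@dataclass
class GaitExample:
    """One labeled walk: a skeleton sequence plus manifest metadata."""

    sequence: SkeletonSequence
    subject_id: str
    gait_label: int
    walk_index: int
    mirrored: bool = False
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.gait_label < 0:
            raise ValidationError("gait_label must be a nonnegative class index")


@dataclass
class GaitDataset:
    """A labeled collection of gait examples with manifest metadata."""

    examples: list[GaitExample]
    class_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = len(self.class_names)
        for ex in self.examples:
            if not 0 <= ex.gait_label < c:
                raise ValidationError(
                    f"gait_label {ex.gait_label} outside [0, {c}) "
                    f"for subject {ex.subject_id!r}"
                )

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def subject_ids(self) -> list[str]:
        """Unique subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for ex in self.examples:
            seen.setdefault(ex.subject_id, None)
        return list(seen)

    def labels(self) -> np.ndarray:
        return np.array([ex.gait_label for ex in self.examples], dtype=np.int64)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_skeleton_sequence(
    path: str | Path, joints: JointSet, fps: float | None = None
) -> SkeletonSequence:
    """Load a sequence from the documented CSV or JSON dialect.

    CSV dialect: header ``frame,joint,x,y,z`` (long form), optionally preceded
    by a ``# fps=<value>`` comment line.  JSON dialect: object with ``fps``,
    ``joints`` and ``frames`` (list of per-frame ``N x 3`` arrays).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _load_json(path, joints, fps)
    return _load_csv(path, joints, fps)


def _load_json(path: Path, joints: JointSet, fps: float | None) -> SkeletonSequence:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    names = payload.get("joints")
    if names is None:
        raise SkeletonFormatError(f"{path}: JSON file lacks 'joints' array")
    if tuple(names) != joints.names:
        unknown = [n for n in names if n not in joints.names]
        if unknown:
            raise SkeletonFormatError(f"{path}: unknown joint name {unknown[0]!r}")
        raise SkeletonFormatError(f"{path}: joint order does not match joint set")
    frames = np.asarray(payload.get("frames", []), dtype=np.float64)
    if frames.ndim != 3:
        raise SkeletonFormatError(f"{path}: 'frames' must be a T x N x 3 array")
    file_fps = float(payload.get("fps", fps if fps is not None else 30.0))
    ts = payload.get("timestamps")
    try:
        return SkeletonSequence(joints, frames, fps if fps is not None else file_fps,
                                None if ts is None else np.asarray(ts))
    except ValidationError as exc:
        raise SkeletonFormatError(f"{path}: {exc}") from exc


def _load_csv(path: Path, joints: JointSet, fps: float | None) -> SkeletonSequence:
    file_fps: float | None = None
    rows: list[tuple[int, str, float, float, float]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("#").strip().split():
                if token.startswith("fps="):
                    file_fps = float(token[4:])
            header_line = fh.readline()
        else:
            header_line = first
        header = [h.strip() for h in header_line.strip().split(",")]
        if header != ["frame", "joint", "x", "y", "z"]:
            raise SkeletonFormatError(
                f"{path}: expected header 'frame,joint,x,y,z', got {header_line.strip()!r}"
            )
        reader = csv.reader(fh)
        for rec in reader:
            if not rec:
                continue
            frame_s, joint, xs, ys, zs = rec
            frame = int(frame_s)
            if joint not in joints.names:
                raise SkeletonFormatError(f"{path}: unknown joint name {joint!r}")
            x, y, z = float(xs), float(ys), float(zs)
            for v in (x, y, z):
                if not np.isfinite(v):
                    raise SkeletonFormatError(
                        f"{path}: non-finite coordinate at frame {frame}, joint {joint!r}"
                    )
            rows.append((frame, joint, x, y, z))
    if not rows:
        raise SkeletonFormatError(f"{path}: file contains no data rows")
    frame_ids = sorted({r[0] for r in rows})
    frame_pos = {f: i for i, f in enumerate(frame_ids)}
    T, N = len(frame_ids), joints.n_joints
    positions = np.full((T, N, 3), np.nan)
    for frame, joint, x, y, z in rows:
        positions[frame_pos[frame], joints.index(joint)] = (x, y, z)
    for t in range(T):
        missing = np.argwhere(np.isnan(positions[t, :, 0])).ravel()
        if missing.size:
            raise SkeletonFormatError(
                f"{path}: frame {frame_ids[t]} is missing joint "
                f"{joints.names[missing[0]]!r}"
            )
    use_fps = fps if fps is not None else (file_fps if file_fps is not None else 30.0)
    return SkeletonSequence(joints, positions, use_fps)


def save_skeleton_sequence(seq: SkeletonSequence, path: str | Path) -> None:
    """Write a sequence in the CSV dialect (or JSON if the path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "fps": seq.fps,
            "joints": list(seq.joints.names),
            "frames": seq.positions.tolist(),
        }
        if seq.frame_timestamps is not None:
            payload["timestamps"] = seq.frame_timestamps.tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# fps={seq.fps!r}\n")
        fh.write("frame,joint,x,y,z\n")
        writer = csv.writer(fh)
        for t in range(seq.n_frames):
            for n, name in enumerate(seq.joints.names):
                x, y, z = seq.positions[t, n]
                writer.writerow([t, name, repr(float(x)), repr(float(y)), repr(float(z))])


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def apply_calibration(seq: SkeletonSequence, tf: RigidTransform) -> SkeletonSequence:
    """Map every joint position through ``p -> R p + t``; fps is unchanged."""
    out = seq.copy()
    out.positions = tf.apply(seq.positions)
    return out


def mirror_sequence(seq: SkeletonSequence) -> SkeletonSequence:
    """Reverse left and right: negate the lateral axis and swap paired joints."""
    pairs = seq.joints.lr_pairs()
    out = seq.copy()
    out.positions[..., LATERAL_AXIS] *= -1.0
    for left, right in pairs:
        li, ri = seq.joints.index(left), seq.joints.index(right)
        out.positions[:, [li, ri], :] = out.positions[:, [ri, li], :]
    return out


def _mirror_ground_truth(gt: dict | None) -> dict | None:
    if gt is None:
        return None
    out = dict(gt)
    for key in list(out):
        if key.endswith("_left"):
            other = key[: -len("_left")] + "_right"
            if other in gt:
                out[key], out[other] = gt[other], gt[key]
    return out


def mirror_lr(example: GaitExample) -> GaitExample:
    """Left/right mirroring augmentation; label and subject are preserved."""
    return GaitExample(
        sequence=mirror_sequence(example.sequence),
        subject_id=example.subject_id,
        gait_label=example.gait_label,
        walk_index=example.walk_index,
        mirrored=not example.mirrored,
        ground_truth=_mirror_ground_truth(example.ground_truth),
    )


def window_sequence(
    seq: SkeletonSequence, window: int, tail_drop: int = 0
) -> SkeletonSequence:
    """Keep frames ``[T - tail_drop - window, T - tail_drop)`` (0-based, half-open).

    The last ``tail_drop`` frames are discarded and the ``window`` frames
    immediately preceding them are retained.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    if tail_drop < 0:
        raise ValidationError("tail_drop must be nonnegative")
    T = seq.n_frames
    needed = window + tail_drop
    if T < needed:
        raise ValidationError(
            f"sequence too short: {T} frames, need at least {needed}"
        )
    start, stop = T - tail_drop - window, T - tail_drop
    ts = None
    if seq.frame_timestamps is not None:
        ts = seq.frame_timestamps[start:stop].copy()
    return SkeletonSequence(seq.joints, seq.positions[start:stop].copy(), seq.fps, ts)


def filter_short_sequences(ds: GaitDataset, min_frames: int) -> GaitDataset:
    """Retain only examples whose sequence has at least ``min_frames`` frames."""
    if min_frames <= 0:
        raise ValidationError("min_frames must be positive")
    kept = [ex for ex in ds.examples if ex.sequence.n_frames >= min_frames]
    removed = len(ds.examples) - len(kept)
    if removed:
        log.info("filter_short_sequences: removed %d of %d examples (< %d frames)",
                 removed, len(ds.examples), min_frames)
    provenance = dict(ds.provenance)
    provenance["short_sequence_exclusions"] = (
        provenance.get("short_sequence_exclusions", 0) + removed
    )
    return GaitDataset(kept, ds.class_names, provenance)


# ---------------------------------------------------------------------------
# dataset I/O (manifest + per-example skeleton files)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["path", "subject_id", "gait_label", "walk_index", "mirrored"]


def save_dataset(ds: GaitDataset, directory: str | Path) -> Path:
    """Write per-example CSV skeleton files plus a ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    with open(manifest_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for i, ex in enumerate(ds.examples):
            rel = f"example_{i:05d}.csv"
            save_skeleton_sequence(ex.sequence, directory / rel)
            writer.writerow([rel, ex.subject_id, ex.gait_label, ex.walk_index,
                             int(ex.mirrored)])
    with open(directory / "classes.json", "w", encoding="utf-8") as fh:
        json.dump({"class_names": list(ds.class_names), "provenance": _jsonable(ds.provenance)}, fh)
    return manifest_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_dataset(
    manifest_path: str | Path, joints: JointSet | None = None,
    class_names: Sequence[str] | None = None,
) -> GaitDataset:
    """Load a dataset from a manifest CSV written by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    joints = joints if joints is not None else default_joint_set()
    provenance: dict = {}
    if class_names is None:
        classes_file = directory / "classes.json"
        if classes_file.exists():
            with open(classes_file, "r", encoding="utf-8") as fh:
                meta = json.load(fh)
            class_names = meta["class_names"]
            provenance = meta.get("provenance", {})
    examples: list[GaitExample] = []
    max_label = -1
    with open(manifest_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            seq = load_skeleton_sequence(directory / row["path"], joints)
            label = int(row["gait_label"])
            max_label = max(max_label, label)
            examples.append(GaitExample(
                sequence=seq,
                subject_id=row["subject_id"],
                gait_label=label,
                walk_index=int(row["walk_index"]),
                mirrored=bool(int(row.get("mirrored", "0") or 0)),
            ))
    if class_names is None:
        class_names = [f"class_{i}" for i in range(max_label + 1)]
    return GaitDataset(examples, tuple(class_names), provenance)
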