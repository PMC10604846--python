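"""Per-frame joint bending angles and link angles.

Two angle families are extracted from a skeleton sequence:

* **bending angles** — the interior angle at a joint between its two adjacent
  limb segments, computed with the law-of-cosines form over the triangle
  formed by the joint and its two connected joints;
* **link angles** — the angle between a limb-segment vector and one of the
  coordinate axes.

The default configuration yields 25 angle columns per frame: six bending
angles (left/right hip, knee, ankle), six lower-limb links (thigh, shank,
foot per side) about all three axes, and the trunk link about the lateral
axis only.  All angles are reported in degrees within [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .skeleton import SkeletonSequence

__all__ = [
    "BendingAngleDef",
    "LinkDef",
    "AngleSequence",
    "AngleConfig",
    "default_angle_config",
    "bending_angle",
    "link_angle",
    "extract_angle_matrix",
]

#: minimum limb-vector length (meters) below which geometry is degenerate
DEGENERACY_EPS = 1e-8

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class BendingAngleDef:
    """Bending angle at vertex ``alpha`` between rays to ``beta`` and ``gamma``."""

    alpha: str
    beta: str
    gamma: str

    def __post_init__(self) -> None:
        if len({self.alpha, self.beta, self.gamma}) != 3:
            raise ValidationError("bending angle requires three distinct joints")

    @property
    def label(self) -> str:
        return f"bend_{self.alpha}"


@dataclass(frozen=True)
class LinkDef:
    """A limb link from joint ``n`` (proximal) to joint ``m`` (distal).

    The link vector is ``v_m - v_n`` with ``m`` the distal joint.
    """

    name: str
    m: str
    n: str
    axes: tuple[str, ...] = ("x", "y", "z")

    def __post_init__(self) -> None:
        if self.m == self.n:
            raise ValidationError("link endpoints must differ")
        if not self.axes:
            raise ValidationError("link must use at least one axis")
        bad = [a for a in self.axes if a not in _AXES]
        if bad:
            raise ValidationError(f"unknown axes {bad}")


@dataclass
class AngleSequence:
    """``T x A`` matrix of per-frame angles in degrees with labeled columns."""

    values: np.ndarray
    column_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("angle values must be a T x A matrix")
        if self.values.shape[1] != len(self.column_labels):
            raise ValidationError("number of labels must match number of columns")
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > 180.0 + 1e-9
        ):
            raise ValidationError("angles must lie in [0, 180] degrees")

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AngleConfig:
    """Ordered bending-angle and link-angle column plan."""

    bending: tuple[BendingAngleDef, ...]
    links: tuple[LinkDef, ...]

    @property
    def n_angles(self) -> int:
        return len(self.bending) + sum(len(l.axes) for l in self.links)

    def column_labels(self) -> tuple[str, ...]:
        labels = [b.label for b in self.bending]
        for link in self.links:
            labels.extend(f"link_{link.name}_{axis}" for axis in link.axes)
        return tuple(labels)


def default_angle_config() -> AngleConfig:
    """The 25-column default: 6 bending + 6 links x 3 axes + trunk about x."""
    bending = (
        BendingAngleDef("hip_left", "pelvis", "knee_left"),
        BendingAngleDef("hip_right", "pelvis", "knee_right"),
        BendingAngleDef("knee_left", "hip_left", "ankle_left"),
        BendingAngleDef("knee_right", "hip_right", "ankle_right"),
        BendingAngleDef("ankle_left", "knee_left", "foot_left"),
        BendingAngleDef("ankle_right", "knee_right", "foot_right"),
    )
    links = (
        LinkDef("thigh_left", m="knee_left", n="hip_left"),
        LinkDef("thigh_right", m="knee_right", n="hip_right"),
        LinkDef("shank_left", m="ankle_left", n="knee_left"),
        LinkDef("shank_right", m="ankle_right", n="knee_right"),
        LinkDef("foot_left", m="foot_left", n="ankle_left"),
        LinkDef("foot_right", m="foot_right", n="ankle_right"),
        LinkDef("trunk", m="head", n="pelvis", axes=("x",)),
    )
    return AngleConfig(bending=bending, links=links)


def bending_angle(seq: SkeletonSequence, definition: BendingAngleDef) -> np.ndarray:
    """Per-frame bending angle at ``alpha`` in degrees, law-of-cosines form.

    theta = arccos[(|b - a|^2 + |g - a|^2 - |g - b|^2) / (2 |b - a| |g - a|)]
    with the cosine argument clamped to [-1, 1].
    """
    a = seq.joint_trajectory(definition.alpha)
    b = seq.joint_trajectory(definition.beta)
    g = seq.joint_trajectory(definition.gamma)
    ab = np.linalg.norm(b - a, axis=1)
    ag = np.linalg.norm(g - a, axis=1)
    bg2 = np.sum((g - b) ** 2, axis=1)
    for norms, other in ((ab, definition.beta), (ag, definition.gamma)):
        short = np.argwhere(norms < DEGENERACY_EPS).ravel()
        if short.size:
            raise DegenerateGeometryError(
                f"degenerate limb vector {definition.alpha}->{other} "
                f"at frame {short[0]}",
                frame=int(short[0]),
            )
    cos = (ab**2 + ag**2 - bg2) / (2.0 * ab * ag)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def link_angle(seq: SkeletonSequence, link: LinkDef, axis: str) -> np.ndarray:
    """Per-frame angle between the link vector ``v_m - v_n`` and a unit axis."""
    if axis not in _AXES:
        raise ValidationError(f"unknown axis {axis!r}")
    v = seq.joint_trajectory(link.m) - seq.joint_trajectory(link.n)
    norms = np.linalg.norm(v, axis=1)
    short = np.argwhere(norms < DEGENERACY_EPS).ravel()
    if short.size:
        raise DegenerateGeometryError(
            f"zero-length link {link.name!r} at frame {short[0]}",
            frame=int(short[0]),
        )
    cos = v[:, _AXES[axis]] / norms
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def extract_angle_matrix(
    seq: SkeletonSequence, config: AngleConfig | None = None
) -> AngleSequence:
    """Assemble the full ``T x A`` angle matrix (default A = 25)."""
    config = config if config is not None else default_angle_config()
    columns: list[np.ndarray] = []
    for bdef in config.bending:
        try:
            columns.append(bending_angle(seq, bdef))
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"column {bdef.label!r}: {exc}", frame=exc.frame
            ) from exc
    for link in config.links:
        for axis in link.axes:
            try:
                columns.append(link_angle(seq, link, axis))
            except DegenerateGeometryError as exc:
                raise DegenerateGeometryError(
                    f"column 'link_{link.name}_{axis}': {exc}", frame=exc.frame
                ) from exc
    values = np.stack(columns, axis=1) if columns else np.zeros((seq.n_frames, 0))
    return AngleSequence(values=values, column_labels=config.column_labels())
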