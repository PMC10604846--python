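"""Build the three model input views for a dataset of gait examples.

Every example is windowed to a common length, then converted into the raw
skeleton tensor ``(3, T, N)``, the joint-angle matrix ``(T, A)`` and the
gait-parameter vector ``(P,)`` consumed by the hybrid model branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import AngleConfig, extract_angle_matrix
from .errors import ValidationError
from .gait import compute_parameter_vector
from .skeleton import GaitDataset, window_sequence

__all__ = ["DatasetViews", "build_views"]


@dataclass
class DatasetViews:
    """Stacked per-example input views plus labels and subject ids."""

    skeleton: np.ndarray | None
    angles: np.ndarray | None
    params: np.ndarray | None
    labels: np.ndarray
    subjects: list[str]

    def views(self) -> dict[str, np.ndarray]:
        out = {}
        if self.skeleton is not None:
            out["skeleton"] = self.skeleton
        if self.angles is not None:
            out["angles"] = self.angles
        if self.params is not None:
            out["params"] = self.params
        return out

    def subset(self, idx: np.ndarray) -> "DatasetViews":
        pick = lambda a: None if a is None else a[idx]
        return DatasetViews(
            skeleton=pick(self.skeleton),
            angles=pick(self.angles),
            params=pick(self.params),
            labels=self.labels[idx],
            subjects=[self.subjects[i] for i in idx],
        )


def build_views(
    ds: GaitDataset,
    window: int | None = 100,
    tail_drop: int = 10,
    angle_config: AngleConfig | None = None,
    branches: tuple[str, ...] = ("skeleton", "angles", "params"),
) -> DatasetViews:
    """Window every example and extract the requested input views.

    Angle and parameter extraction operate on the windowed sequence so that
    all branches see the same frames.  With ``window=None`` the sequences
    must already share a common length.
    """
    if not ds.examples:
        raise ValidationError("empty dataset")
    skeletons, angles, params = [], [], []
    labels, subjects = [], []
    for ex in ds.examples:
        seq = ex.sequence
        if window is not None:
            seq = window_sequence(seq, window, tail_drop)
        if "skeleton" in branches:
            skeletons.append(seq.positions.transpose(2, 0, 1))  # (3, T, N)
        if "angles" in branches:
            angles.append(extract_angle_matrix(seq, angle_config).values)
        if "params" in branches:
            params.append(compute_parameter_vector(seq).values)
        labels.append(ex.gait_label)
        subjects.append(ex.subject_id)
    lengths = {a.shape[1] if a.ndim == 3 else a.shape[0]
               for a in (skeletons or angles)}
    if window is None and len(lengths) > 1:
        raise ValidationError(
            "sequences have unequal lengths; pass a window to align them")
    return DatasetViews(
        skeleton=np.stack(skeletons) if skeletons else None,
        angles=np.stack(angles) if angles else None,
        params=np.stack(params) if params else None,
        labels=np.asarray(labels, dtype=np.int64),
        subjects=subjects,
    )
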