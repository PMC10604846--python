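"""Shared fixtures: joint sets, simple synthetic sequences, simulated walks."""

from __future__ import annotations

import numpy as np
import pytest

from gaitrec import (
    GaitDataset,
    GaitExample,
    SkeletonSequence,
    default_joint_set,
)
from gaitrec.synth import SubjectProfile, simulate_walk, style_for_class


@pytest.fixture(scope="session")
def joints():
    return default_joint_set()


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile.from_seed("S000", 42)


@pytest.fixture(scope="session")
def normal_walk(subject):
    """A clean, noiseless normal walk with ground truth."""
    style = style_for_class("normal", subject.affected_side,
                            scale=subject.step_scale)
    return simulate_walk(style, subject, n_frames=150, fps=30.0, seed=1,
                         noise_std=0.0)


@pytest.fixture(scope="session")
def noisy_walk(subject):
    style = style_for_class("normal", subject.affected_side,
                            scale=subject.step_scale)
    return simulate_walk(style, subject, n_frames=120, fps=30.0, seed=2,
                         noise_std=0.003)


@pytest.fixture
def static_sequence(joints):
    """A standing (motionless) skeleton, pelvis-up trunk exactly vertical."""
    pos = np.zeros((40, joints.n_joints, 3))
    layout = {
        "pelvis": (0.0, 0.9, 0.0),
        "spine_navel": (0.0, 1.1, 0.0),
        "spine_chest": (0.0, 1.3, 0.0),
        "neck": (0.0, 1.5, 0.0),
        "head": (0.0, 1.65, 0.0),
        "shoulder_left": (0.2, 1.45, 0.0),
        "elbow_left": (0.25, 1.15, 0.0),
        "wrist_left": (0.27, 0.9, 0.0),
        "shoulder_right": (-0.2, 1.45, 0.0),
        "elbow_right": (-0.25, 1.15, 0.0),
        "wrist_right": (-0.27, 0.9, 0.0),
        "hip_left": (0.1, 0.85, 0.0),
        "knee_left": (0.1, 0.45, 0.0),
        "ankle_left": (0.1, 0.08, 0.0),
        "foot_left": (0.1, 0.05, 0.15),
        "hip_right": (-0.1, 0.85, 0.0),
        "knee_right": (-0.1, 0.45, 0.0),
        "ankle_right": (-0.1, 0.08, 0.0),
        "foot_right": (-0.1, 0.05, 0.15),
    }
    for name, xyz in layout.items():
        pos[:, joints.index(name), :] = xyz
    return SkeletonSequence(joints, pos, fps=30.0)


def make_dataset(lengths, joints, label=0, subject_prefix="S", class_names=("a", "b")):
    """Tiny dataset whose examples have the given sequence lengths."""
    rng = np.random.default_rng(0)
    examples = []
    for i, t in enumerate(lengths):
        pos = rng.normal(size=(t, joints.n_joints, 3))
        seq = SkeletonSequence(joints, pos, fps=30.0)
        examples.append(GaitExample(sequence=seq,
                                    subject_id=f"{subject_prefix}{i:03d}",
                                    gait_label=label, walk_index=0))
    return GaitDataset(examples, class_names)
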