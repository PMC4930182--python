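"""Shared fixtures: programmatically built recordings (no stored data files)."""

from __future__ import annotations

import numpy as np
import pytest

from fmscore.motion_io import FMAItem, JOINTS, MotionRecording
from fmscore.synthdata import min_jerk_trajectory


def make_recording(
    t: np.ndarray,
    xyz: np.ndarray,
    side: str = "left",
    item: FMAItem = FMAItem.ELBOW_FLEXION,
    frame_rate: float = 30.0,
    subject_id: str = "T001",
) -> MotionRecording:
    return MotionRecording(
        subject_id=subject_id, side=side, item=item,
        frame_rate=frame_rate, t=t, xyz=xyz,
    )


def static_pose(n: int, fs: float = 30.0) -> MotionRecording:
    """A plausible static seated skeleton: n identical frames."""
    xyz = np.zeros((n, len(JOINTS), 3))
    pose = {
        "head": (0.0, 0.75, 2.4), "shoulder_center": (0.0, 0.5, 2.4),
        "shoulder_l": (0.18, 0.5, 2.4), "shoulder_r": (-0.18, 0.5, 2.4),
        "elbow_l": (0.2, 0.22, 2.42), "elbow_r": (-0.2, 0.22, 2.42),
        "wrist_l": (0.22, -0.04, 2.44), "wrist_r": (-0.22, -0.04, 2.44),
        "hand_l": (0.22, -0.12, 2.44), "hand_r": (-0.22, -0.12, 2.44),
    }
    for j, name in enumerate(JOINTS):
        xyz[:, j, :] = pose[name]
    return make_recording(np.arange(n) / fs, xyz, frame_rate=fs)


def single_joint_min_jerk(
    D: float = 0.3, T: float = 2.0, fs: float = 300.0, joint: str = "hand_l"
) -> MotionRecording:
    """All joints static except one moving on a 1-D minimum-jerk profile."""
    t, x = min_jerk_trajectory(D, T, fs)
    rec = static_pose(t.size, fs)
    rec.t = t
    j = JOINTS.index(joint)
    rec.xyz[:, j, 0] = rec.xyz[0, j, 0] + x
    return rec


def random_recording(rng: np.random.Generator, n: int = 20) -> MotionRecording:
    """A finite, strictly-timestamped random recording (for property tests)."""
    rec = static_pose(n)
    rec.xyz = rec.xyz + rng.normal(0.0, 0.05, rec.xyz.shape)
    return rec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def still_move_still() -> MotionRecording:
    """1 s still, 2 s minimum-jerk reach, 1 s still at 30 Hz (onset frame 30)."""
    fs = 30.0
    t_m, x = min_jerk_trajectory(0.4, 2.0, fs)
    n_pad = 30
    prof = np.concatenate([np.zeros(n_pad), x, np.full(n_pad, x[-1])])
    rec = static_pose(prof.size, fs)
    for joint in ("hand_l", "wrist_l"):
        j = JOINTS.index(joint)
        rec.xyz[:, j, 1] = rec.xyz[0, j, 1] + prof
    return rec
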