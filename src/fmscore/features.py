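"""Kinematic feature extraction for per-item score prediction.

From each clipped, pose-normalized recording a fixed-order vector of roughly
one hundred scalars is assembled: summary statistics (min, max, range,
variance, mean) of a versioned roster of joint-angle and joint-distance time
series plus per-axis hand/wrist/elbow displacements, the bounding-rectangle
area of the hand path in the frontal plane, the dimensionless normalized
jerk, and the movement duration.  Range and variance features carry most of
the score signal because the range of motion grows with the FMA score.

The roster is identical for all items and versioned; a trained model stores
the roster version and feature names so stale models cannot silently be
applied to differently laid-out vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMotionError, FeatureError
from .motion_io import FMAItem, MotionRecording
from . import smoothness

ROSTER_VERSION = "1.0"

SUMMARY_NAMES = ("min", "max", "range", "var", "mean")

# (name, a, b, c): angle at vertex b between rays b->a and b->c, moving side.
ANGLE_ROSTER = (
    ("elbow_angle", "shoulder_l", "elbow_l", "wrist_l"),
    ("shoulder_angle", "shoulder_center", "shoulder_l", "elbow_l"),
    ("wrist_angle", "elbow_l", "wrist_l", "hand_l"),
    ("arm_elevation_angle", "head", "shoulder_center", "hand_l"),
)

# (name, a, b): Euclidean distance between two joints, moving side.
DISTANCE_ROSTER = (
    ("hand_shoulder", "hand_l", "shoulder_l"),
    ("hand_head", "hand_l", "head"),
    ("elbow_head", "elbow_l", "head"),
    ("hand_shoulder_center", "hand_l", "shoulder_center"),
    ("wrist_head", "wrist_l", "head"),
    ("wrist_shoulder_center", "wrist_l", "shoulder_center"),
    ("elbow_shoulder_center", "elbow_l", "shoulder_center"),
)

# per-axis displacement from the first frame
DISPLACEMENT_JOINTS = ("hand_l", "wrist_l", "elbow_l")
AXES = ("x", "y", "z")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order kinematic summary of one recording for one item."""

    item: FMAItem
    names: tuple[str, ...]
    values: np.ndarray
    provenance: str = ""
    roster_version: str = ROSTER_VERSION

    def __post_init__(self) -> None:
        if len(self.names) != self.values.size:
            raise FeatureError("feature names and values disagree in length")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise FeatureError(f"non-finite features: {', '.join(bad)}")


def joint_angle_series(
    rec: MotionRecording, a: str, b: str, c: str
) -> np.ndarray:
    """Per-frame angle (degrees, [0, 180]) at vertex ``b`` between rays to ``a`` and ``c``.

    Frames where either ray has zero length yield NaN.
    """
    u = rec.joint(a) - rec.joint(b)
    v = rec.joint(c) - rec.joint(b)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, np.einsum("ij,ij->i", u, v) / denom, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def joint_distance_series(rec: MotionRecording, a: str, b: str) -> np.ndarray:
    """Per-frame Euclidean distance between two joints (normalized units)."""
    return np.linalg.norm(rec.joint(a) - rec.joint(b), axis=1)


def summarize_series(s: np.ndarray) -> dict[str, float]:
    """Summary statistics of one series: min, max, range, variance, mean.

    NaN frames (flagged degenerate geometry) are excluded; an all-NaN series
    raises :class:`FeatureError`.
    """
    s = np.asarray(s, dtype=float)
    valid = s[np.isfinite(s)]
    if valid.size == 0:
        raise FeatureError("all-NaN series; no frames to summarize")
    return {
        "min": float(valid.min()),
        "max": float(valid.max()),
        "range": float(valid.max() - valid.min()),
        "var": float(np.var(valid)),
        "mean": float(valid.mean()),
    }


def feature_names(item: FMAItem | None = None) -> tuple[str, ...]:
    """The fixed, versioned feature-name order (identical across items)."""
    names: list[str] = []
    series = [name for name, *_ in ANGLE_ROSTER]
    series += [f"dist_{name}" for name, *_ in DISTANCE_ROSTER]
    series += [
        f"disp_{joint[:-2]}_{axis}" for joint in DISPLACEMENT_JOINTS for axis in AXES
    ]
    for base in series:
        names.extend(f"{base}_{stat}" for stat in SUMMARY_NAMES)
    names += ["hand_bounding_rect_area_xy", "normalized_jerk", "duration"]
    return tuple(names)


N_FEATURES = len(feature_names())


def extract_features(
    rec: MotionRecording, item: FMAItem | None = None, smooth_jerk: bool = True
) -> FeatureVector:
    """Assemble the deterministic fixed-order feature vector of one recording.

    ``rec`` must be clipped and pose-normalized (moving side = left).  The
    normalized-jerk feature uses Savitzky-Golay-smoothed derivatives by
    default, appropriate for jittery sensor data; a recording with no
    measurable displacement (a genuine score-0 attempt) gets jerk 0.
    """
    item = item or rec.item
    values: list[float] = []
    try:
        for name, a, b, c in ANGLE_ROSTER:
            values.extend(summarize_series(joint_angle_series(rec, a, b, c)).values())
        for name, a, b in DISTANCE_ROSTER:
            values.extend(summarize_series(joint_distance_series(rec, a, b)).values())
        for joint in DISPLACEMENT_JOINTS:
            disp = rec.joint(joint) - rec.joint(joint)[0]
            for ax in range(3):
                values.extend(summarize_series(disp[:, ax]).values())
    except FeatureError as exc:
        raise FeatureError(f"{rec.subject_id}/{item.value}: {exc}") from exc

    hand = rec.joint("hand_l")
    area = float(np.ptp(hand[:, 0]) * np.ptp(hand[:, 1]))
    values.append(area)
    try:
        nj = smoothness.normalized_jerk(rec, smooth=smooth_jerk).normalized_jerk
    except DegenerateMotionError:
        nj = 0.0
    values.append(nj)
    values.append(rec.duration)

    return FeatureVector(
        item=item,
        names=feature_names(item),
        values=np.asarray(values, dtype=float),
        provenance=f"{rec.subject_id}/{rec.side}/{rec.item.value}",
    )
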