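"""Mirroring, motion clipping and pose normalization of skeletal recordings.

Right-arm recordings are mirrored to the left through the subject's sagittal
plane so both arms share one coordinate frame for learning.  Still frames at
the start and end of an attempt are clipped by thresholding the smoothed
per-frame displacement of the moving hand.  Finally every joint is expressed
relative to the initial shoulder-center position and divided by the summed
arm-segment length (wrist-elbow + elbow-shoulder + shoulder-shoulder_center),
which removes seating position and body size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSkeletonError, NoMotionError, ValidationError
from .motion_io import JOINT_INDEX, JOINTS, MotionRecording

#: Default clipping parameters (dimensionless displacement per frame; frames).
CLIP_THRESHOLD = 0.002
CLIP_MARGIN = 5
CLIP_SMOOTH_WINDOW = 5

_MIN_SEGMENT_SUM = 1e-6


@dataclass(frozen=True)
class ClipWindow:
    """Half-open frame window ``[start, end)`` and its time bounds."""

    start: int
    end: int
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError("clip window must satisfy 0 <= start < end")
        if not self.t1 < self.t2:
            raise ValidationError("clip window must satisfy T1 < T2")


def _swap_lr(xyz: np.ndarray) -> np.ndarray:
    out = xyz.copy()
    for name in ("shoulder", "elbow", "wrist", "hand"):
        li, ri = JOINT_INDEX[f"{name}_l"], JOINT_INDEX[f"{name}_r"]
        out[:, li, :], out[:, ri, :] = xyz[:, ri, :], xyz[:, li, :]
    return out


def mirror_to_left(rec: MotionRecording) -> MotionRecording:
    """Reflect a right-side recording across the sagittal plane.

    The sagittal plane is approximated as the vertical plane through the
    first-frame shoulder center with normal along x (no torso re-orientation).
    Left/right joint labels are swapped so the moving arm becomes the left
    one.  Left-side recordings are returned unchanged.  Reflection preserves
    all inter-joint distances and timestamps.
    """
    if rec.side == "left":
        return rec
    x_sc = rec.xyz[0, JOINT_INDEX["shoulder_center"], 0]
    xyz = _swap_lr(rec.xyz)
    xyz[:, :, 0] = 2.0 * x_sc - xyz[:, :, 0]
    return rec.copy(side="left", xyz=xyz)


def resample_uniform(rec: MotionRecording, rtol: float = 1e-3) -> MotionRecording:
    """Linearly interpolate onto a uniform grid at the nominal frame rate.

    Recordings whose timestamps are already uniform (to ``rtol`` of the
    nominal period) are returned unchanged; downstream finite differences
    assume uniform sampling.
    """
    dt = 1.0 / rec.frame_rate
    diffs = np.diff(rec.t)
    if np.allclose(diffs, dt, rtol=rtol, atol=rtol * dt):
        return rec
    n = max(2, int(round(rec.duration / dt)) + 1)
    t_new = rec.t[0] + dt * np.arange(n)
    t_new = t_new[t_new <= rec.t[-1] + 1e-12]
    flat = rec.xyz.reshape(rec.n_frames, -1)
    interp = np.empty((t_new.size, flat.shape[1]))
    for j in range(flat.shape[1]):
        interp[:, j] = np.interp(t_new, rec.t, flat[:, j])
    return rec.copy(t=t_new, xyz=interp.reshape(t_new.size, len(JOINTS), 3))


def body_segment_length(
    rec: MotionRecording, side: str | None = None, per_frame_mean: bool = True
) -> float:
    """Summed arm-segment length: |wrist-elbow| + |elbow-shoulder| + |shoulder-shoulder_center|.

    Averaged over frames by default to damp sensor jitter; set
    ``per_frame_mean=False`` to use the first frame only.
    """
    s = (side or rec.side)[0]
    wrist = rec.joint(f"wrist_{s}")
    elbow = rec.joint(f"elbow_{s}")
    shoulder = rec.joint(f"shoulder_{s}")
    sc = rec.joint("shoulder_center")
    lengths = (
        np.linalg.norm(wrist - elbow, axis=1)
        + np.linalg.norm(elbow - shoulder, axis=1)
        + np.linalg.norm(shoulder - sc, axis=1)
    )
    return float(lengths.mean() if per_frame_mean else lengths[0])


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad : pad + x.size]


def clip_motion(
    rec: MotionRecording,
    threshold: float = CLIP_THRESHOLD,
    margin: int = CLIP_MARGIN,
    smooth_window: int = CLIP_SMOOTH_WINDOW,
    joint: str | None = None,
) -> tuple[MotionRecording, ClipWindow]:
    """Remove still frames before and after the motion.

    The per-frame displacement of the moving-side hand joint (configurable via
    ``joint``), divided by the body-segment length so the threshold is
    dimensionless, is smoothed with a ``smooth_window``-frame moving average
    and thresholded.  The window spans the first through last frame above
    threshold, extended by ``margin`` frames on each side and clamped to the
    recording.

    Raises :class:`NoMotionError` if no frame exceeds the threshold.
    """
    rec = resample_uniform(rec)
    joint = joint or f"hand_{rec.side[0]}"
    if joint == "max":
        disp = np.linalg.norm(np.diff(rec.xyz, axis=0), axis=2).max(axis=1)
    else:
        disp = np.linalg.norm(np.diff(rec.joint(joint), axis=0), axis=1)
    scale = body_segment_length(rec)
    if scale < _MIN_SEGMENT_SUM:
        raise DegenerateSkeletonError("body segment length is ~0; cannot clip")
    smoothed = _moving_average(disp / scale, smooth_window)
    active = np.flatnonzero(smoothed > threshold)
    if active.size == 0:
        raise NoMotionError(
            f"no frame-to-frame displacement above threshold {threshold}"
        )
    # displacement i couples frames i and i+1
    start = max(0, int(active[0]) - margin)
    end = min(rec.n_frames, int(active[-1]) + 2 + margin)
    window = ClipWindow(start=start, end=end, t1=float(rec.t[start]), t2=float(rec.t[end - 1]))
    clipped = rec.copy(t=rec.t[start:end], xyz=rec.xyz[start:end])
    return clipped, window


def normalize_pose(
    rec: MotionRecording, per_frame_mean: bool = True
) -> MotionRecording:
    """Translate by minus the initial shoulder center, divide by body size.

    The divisor is the summed arm-segment length of the moving side (see
    :func:`body_segment_length`).  The output is dimensionless and invariant
    under global translation and uniform scaling of the input.
    """
    scale = body_segment_length(rec, per_frame_mean=per_frame_mean)
    if scale < _MIN_SEGMENT_SUM:
        raise DegenerateSkeletonError(
            f"summed segment length {scale:.2e} below tolerance"
        )
    origin = rec.xyz[0, JOINT_INDEX["shoulder_center"], :]
    return rec.copy(xyz=(rec.xyz - origin) / scale)


def preprocess_recording(
    rec: MotionRecording,
    threshold: float = CLIP_THRESHOLD,
    margin: int = CLIP_MARGIN,
    on_no_motion: str = "raise",
) -> tuple[MotionRecording, ClipWindow]:
    """Full chain: mirror to left, resample, clip, normalize.

    ``on_no_motion="full"`` keeps the whole recording when clipping finds no
    motion (an FMA score-0 attempt genuinely contains none, yet still has to
    be scored); ``"raise"`` propagates :class:`NoMotionError`.
    """
    rec = mirror_to_left(rec)
    rec = resample_uniform(rec)
    try:
        clipped, window = clip_motion(rec, threshold=threshold, margin=margin)
    except NoMotionError:
        if on_no_motion != "full":
            raise
        clipped = rec
        window = ClipWindow(0, rec.n_frames, float(rec.t[0]), float(rec.t[-1]))
    return normalize_pose(clipped), window
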