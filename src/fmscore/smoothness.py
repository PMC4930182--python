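"""Movement-smoothness analysis: integrated squared jerk, dimensionless form.

Jerk is the third time-derivative of position.  The movement vector P(t)
stacks the six moving-side joints (head, shoulder center, shoulder, elbow,
wrist, hand) in three dimensions, so Jerk(t) is an 18-dimensional vector.
Because the integrated squared jerk carries units of length^2 / duration^5 it
cannot be compared across movements of different speed and extent; it is made
dimensionless by multiplying with duration^5 / length^2, where duration is
the length of the clipped movement [T1, T2] and length is the maximum
distance of the position vector from its value at T1.  The square root is
taken so the statistic is proportional to absolute jerk:

    NJ = sqrt( 1/2 * integral_{T1}^{T2} ||Jerk(t)||^2 dt * duration^5 / length^2 )

A perfectly smooth point-to-point reach (the minimum-jerk quintic) attains
NJ = sqrt(360) ~= 18.97; tremor and corrective submovements raise NJ.  For
cohort statistics NJ is log10-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import butter, filtfilt

from .errors import DegenerateMotionError, InsufficientDataError
from .motion_io import JOINT_INDEX, MotionRecording

#: The five-point third-derivative stencil needs at least this many frames.
_MIN_FRAMES = 7

#: Zero-phase low-pass applied to positions when ``smooth=True``: emulates the
#: joint smoothing of depth-sensor skeleton SDKs.  Voluntary reaching keeps
#: its energy below ~2 Hz, so a 3 Hz cutoff preserves the movement's own
#: jerk while suppressing the broadband sensor jitter that triple
#: differentiation would otherwise amplify by ~fs^3; 4-10 Hz pathological
#: tremor is strongly attenuated in position but remains the dominant,
#: monotone jerk contribution because jerk scales with frequency cubed.
SMOOTH_CUTOFF_HZ = 3.0
SMOOTH_ORDER = 4


def moving_side_joints(side: str) -> list[str]:
    """The six joints entering the 18-dimensional movement vector."""
    s = side[0]
    return ["head", "shoulder_center", f"shoulder_{s}", f"elbow_{s}", f"wrist_{s}", f"hand_{s}"]


@dataclass(frozen=True)
class JerkResult:
    """Smoothness summary of one clipped movement."""

    duration: float  # seconds, T2 - T1
    length: float  # max displacement from the T1 position (input units)
    integrated_squared_jerk: float  # length^2 / duration^5
    normalized_jerk: float  # dimensionless
    log_jerk: float  # log10(normalized_jerk)


def _movement_matrix(rec: MotionRecording) -> np.ndarray:
    idx = [JOINT_INDEX[j] for j in moving_side_joints(rec.side)]
    return rec.xyz[:, idx, :].reshape(rec.n_frames, -1)


def _third_derivative(p: np.ndarray, dt: float) -> np.ndarray:
    """Second-order third derivative along axis 0, full length.

    Central five-point stencil in the interior,
    ``(p[i+2] - 2 p[i+1] + 2 p[i-1] - p[i-2]) / (2 dt^3)``, with one-sided
    second-order stencils at the two frames on each boundary.
    """
    j = np.empty_like(p)
    h3 = dt**3
    j[2:-2] = (p[4:] - 2 * p[3:-1] + 2 * p[1:-3] - p[:-4]) / (2 * h3)
    for i in (0, 1):  # forward: -5/2, 9, -12, 7, -3/2
        j[i] = (
            -2.5 * p[i] + 9 * p[i + 1] - 12 * p[i + 2] + 7 * p[i + 3] - 1.5 * p[i + 4]
        ) / h3
    for i in (-1, -2):  # backward (odd derivative: mirrored signs)
        j[i] = (
            2.5 * p[i] - 9 * p[i - 1] + 12 * p[i - 2] - 7 * p[i - 3] + 1.5 * p[i - 4]
        ) / h3
    return j


def jerk_series(
    rec: MotionRecording, smooth: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Third derivative of the 18-dim movement vector.

    Second-order finite differences (five-point central stencil in the
    interior, one-sided stencils at the boundaries), so the series keeps the
    full frame count and the jerk integral covers all of [T1, T2] -
    point-to-point reaches have their largest jerk exactly at the movement
    boundaries.  With ``smooth=True`` a zero-phase low-pass filter
    (:data:`SMOOTH_CUTOFF_HZ`) is applied to the positions first, which is
    essential for real depth-sensor data (triple differentiation amplifies
    white jitter by ~fs^3) but off by default so the derivative is a pure,
    deterministic stencil.
    """
    if rec.n_frames < _MIN_FRAMES:
        raise InsufficientDataError(
            f"need >= {_MIN_FRAMES} frames for the third derivative, got {rec.n_frames}"
        )
    dt = float(np.median(np.diff(rec.t)))
    p = _movement_matrix(rec)
    if smooth:
        b, a = butter(SMOOTH_ORDER, SMOOTH_CUTOFF_HZ * 2.0 * dt, btype="low")
        padlen = min(3 * max(len(a), len(b)), rec.n_frames - 2)
        p = filtfilt(b, a, p, axis=0, padlen=padlen)
    return rec.t, _third_derivative(p, dt)


def normalized_jerk(
    rec: MotionRecording,
    length_joint: str = "all",
    smooth: bool = False,
) -> JerkResult:
    """Dimensionless normalized jerk of a clipped, uniformly sampled recording.

    ``length_joint="all"`` (default) takes the length scale as the maximum
    Euclidean displacement of the full 18-dim movement vector from its value
    at T1; ``"hand"`` uses the moving hand joint only (the alternative
    reading of "distance of a position vector from the initial").
    """
    duration = rec.duration
    p = _movement_matrix(rec)
    if length_joint == "hand":
        hand = rec.joint(f"hand_{rec.side[0]}")
        disp = np.linalg.norm(hand - hand[0], axis=1)
    else:
        disp = np.linalg.norm(p - p[0], axis=1)
    length = float(disp.max())
    if length <= 0.0:
        raise DegenerateMotionError("zero displacement; length scale undefined")
    times, j = jerk_series(rec, smooth=smooth)
    isj = float(trapezoid(np.sum(j * j, axis=1), times))
    nj = float(np.sqrt(0.5 * isj * duration**5 / length**2))
    return JerkResult(
        duration=duration,
        length=length,
        integrated_squared_jerk=isj,
        normalized_jerk=nj,
        log_jerk=log_jerk(nj) if nj > 0 else float("-inf"),
    )


def log_jerk(nj: float, base: float = 10.0) -> float:
    """Log-transformed normalized jerk (base 10 by default).

    The log transform symmetrizes the heavily right-skewed cohort
    distribution of NJ before paired comparisons.
    """
    if nj <= 0:
        raise ValueError(f"log jerk requires a positive normalized jerk, got {nj}")
    return float(np.log(nj) / np.log(base))
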