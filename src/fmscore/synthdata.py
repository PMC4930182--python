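"""Synthetic upper-limb motion and cohort generator.

Every stage of the scoring pipeline is exercisable without patient data by
synthesizing plausible seated reaching motions: start and end arm poses come
from two-link inverse kinematics on an item-specific wrist path, a shared
minimum-jerk profile carries every joint between the two poses, and the
signal is degraded with band-limited tremor (4-10 Hz, the physiological
range), slow sensor drift and broadband sensor jitter, sampled at 30 Hz with
still padding before and after the movement.

The generative score class controls movement amplitude (score 0: 0-20 % of
the item's full range of motion, score 1: 30-70 %, score 2: 80-100 %) and
movement tempo; tremor amplitude maps inversely onto the Brunnstrom arm
stage.  A synthetic cohort pairs a hemiplegic side (score- and
stage-dependent) with a non-hemiplegic side (full amplitude, minimal tremor)
for each subject, mimicking a bilateral recording session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ValidationError
from .motion_io import (
    JOINT_INDEX,
    JOINTS,
    CohortTable,
    FMAItem,
    MotionRecording,
    MAX_UE_TOTAL,
)
import pandas as pd

# Fixed body geometry (meters): plausibility, not anthropometric fidelity.
UPPER_ARM = 0.28
FOREARM = 0.26
HALF_SHOULDER = 0.18
HAND_OFFSET = 0.08
SHOULDER_CENTER = np.array([0.0, 0.50, 2.40])  # camera coords, x lateral
HEAD = SHOULDER_CENTER + np.array([0.0, 0.25, 0.0])

#: Score class -> admissible movement-amplitude fraction of the full range.
CLASS_AMPLITUDE = {0: (0.0, 0.2), 1: (0.3, 0.7), 2: (0.8, 1.0)}

#: Brunnstrom arm stage -> hemiplegic tremor RMS amplitude (meters).
DEFAULT_TREMOR_BY_STAGE = {1: 0.012, 2: 0.010, 3: 0.008, 4: 0.0055, 5: 0.0035, 6: 0.002}
#: Tremor RMS on the non-hemiplegic side (meters); physiological tremor at
#: the hand is a few tenths of a millimeter.
HEALTHY_TREMOR = 0.0003

#: Wrist path per item: (start, end) offsets from the moving shoulder at full
#: range of motion, in the left-arm frame (x toward the moving side).  All
#: targets stay well inside the two-link reach (|offset| <= ~0.49 of the
#: 0.54 m maximum): near full extension the elbow solution of the inverse
#: kinematics approaches a square-root singularity and a real arm never
#: operates there during these seated test motions.
_REST = (0.02, -0.47, 0.05)
ITEM_PATHS: dict[FMAItem, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    FMAItem.SHOULDER_RETRACTION: (_REST, (0.05, -0.45, 0.13)),
    FMAItem.SHOULDER_ELEVATION: (_REST, (0.05, -0.36, 0.04)),
    FMAItem.SHOULDER_ABDUCTION: (_REST, (0.42, -0.24, 0.0)),
    FMAItem.SHOULDER_EXTERNAL_ROTATION: (_REST, (0.28, -0.32, -0.22)),
    FMAItem.ELBOW_FLEXION: (_REST, (-0.30, 0.10, 0.05)),  # hand to opposite ear
    FMAItem.FOREARM_SUPINATION: (_REST, (0.10, -0.40, -0.25)),
    FMAItem.SHOULDER_ADDUCTION_INTERNAL_ROTATION: ((0.38, -0.28, 0.0), (-0.05, -0.44, -0.05)),
    FMAItem.ELBOW_EXTENSION: ((-0.10, -0.15, -0.10), (0.05, -0.28, -0.36)),
    FMAItem.FOREARM_PRONATION: (_REST, (0.12, -0.38, -0.22)),
    FMAItem.HAND_TO_LUMBAR_SPINE: (_REST, (-0.10, -0.42, 0.18)),
    FMAItem.SHOULDER_FLEXION_0_90: (_REST, (0.05, 0.0, -0.46)),
    FMAItem.SHOULDER_ABDUCTION_0_90: (_REST, (0.46, 0.0, -0.05)),
    FMAItem.SHOULDER_FLEXION_90_180: ((0.05, 0.0, -0.46), (0.05, 0.42, -0.14)),
}


@dataclass
class MotionParams:
    """Generative parameters of one synthetic FMA item attempt."""

    item: FMAItem
    score_class: int
    amplitude_fraction: float
    duration: float = 2.5  # seconds of actual movement
    tremor_amplitude: float = 0.0  # RMS meters at the hand
    tremor_band: tuple[float, float] = (4.0, 10.0)  # Hz
    sensor_noise_sd: float = 0.0003  # meters RMS, broadband jitter, all joints
    sensor_drift_sd: float = 0.002  # meters RMS, slow (<~0.3 Hz) wander
    seed: int = 0
    side: str = "left"
    still_padding: float = 1.0  # seconds of rest before and after
    frame_rate: float = 30.0
    subject_id: str = "synth"

    def __post_init__(self) -> None:
        if self.score_class not in CLASS_AMPLITUDE:
            raise ValidationError("score_class must be 0, 1 or 2")
        lo, hi = CLASS_AMPLITUDE[self.score_class]
        if not (lo <= self.amplitude_fraction <= hi):
            raise ValidationError(
                f"amplitude_fraction {self.amplitude_fraction} outside the "
                f"class-{self.score_class} band [{lo}, {hi}]"
            )
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        nyquist = self.frame_rate / 2.0
        if not (0.0 < self.tremor_band[0] < self.tremor_band[1] < nyquist):
            raise ValidationError(f"tremor band must lie within (0, {nyquist}) Hz")


def min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.asarray(tau, dtype=float)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_trajectory(D: float, T: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """1-D minimum-jerk point-to-point reach of extent ``D`` over ``T`` seconds.

    Returns ``(t, x)`` sampled at ``fs`` Hz with ``x(0) = 0`` and
    ``x(T) = D``; velocity and acceleration vanish at both endpoints and the
    peak speed is 1.875 D/T at mid-movement.
    """
    if D <= 0 or T <= 0 or fs <= 0:
        raise ValidationError("D, T and fs must all be positive")
    n = int(round(T * fs))
    t = np.arange(n + 1) / fs
    return t, D * min_jerk_profile(t / T)


def _two_link_elbow(shoulder: np.ndarray, wrist: np.ndarray) -> np.ndarray:
    """Elbow position of a two-link arm for one shoulder/wrist pose.

    The elbow sits on the circle of intersection of the two segment spheres;
    the bend direction is the component of a fixed down-and-forward reference
    orthogonal to the shoulder-wrist axis, which keeps the elbow below the
    arm in natural seated postures.
    """
    v = wrist - shoulder
    d = float(np.linalg.norm(v))
    d = np.clip(d, abs(UPPER_ARM - FOREARM) + 1e-3, UPPER_ARM + FOREARM - 1e-3)
    u = v / d
    a = (UPPER_ARM**2 - FOREARM**2 + d**2) / (2 * d)
    h = np.sqrt(max(UPPER_ARM**2 - a**2, 0.0))
    g = np.array([0.0, -1.0, -0.3])
    p = g - (g @ u) * u
    if np.linalg.norm(p) < 1e-6:
        g = np.array([0.0, 0.0, -1.0])
        p = g - (g @ u) * u
    p = p / np.linalg.norm(p)
    return shoulder + a * u + h * p


def _band_limited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, shape ``(n, 3)``."""
    white = rng.standard_normal((max(n, 64), 3))
    nyq = fs / 2.0
    b, a = butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass")
    shaped = filtfilt(b, a, white, axis=0)[:n]
    rms = np.sqrt(np.mean(shaped**2, axis=0))
    return shaped / np.maximum(rms, 1e-12)


def synth_motion(params: MotionParams) -> MotionRecording:
    """Generate one synthetic recording, fully reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    fs = params.frame_rate
    n_pad = int(round(params.still_padding * fs))
    n_move = int(round(params.duration * fs)) + 1
    n = 2 * n_pad + n_move

    mirror = 1.0 if params.side == "left" else -1.0
    shoulder = SHOULDER_CENTER + np.array([mirror * HALF_SHOULDER, 0.0, 0.0])
    other_shoulder = SHOULDER_CENTER - np.array([mirror * HALF_SHOULDER, 0.0, 0.0])

    start, end = (np.array(v) for v in ITEM_PATHS[params.item])
    start = start * np.array([mirror, 1.0, 1.0])
    end = end * np.array([mirror, 1.0, 1.0])

    tau = np.arange(n_move) / max(n_move - 1, 1)
    profile = min_jerk_profile(tau)
    profile = np.concatenate(
        [np.zeros(n_pad), profile, np.full(n_pad, profile[-1])]
    )
    # Endpoint arm poses from exact two-link inverse kinematics; in between,
    # every joint translates along its chord with the shared minimum-jerk
    # profile.  This makes the noise-free 18-dim trajectory exactly minimum
    # jerk (dimensionless jerk at the sqrt(360) floor), matching the
    # near-floor smoothness that unimpaired test motions exhibit; the small
    # mid-path segment-length slack of the chord shortcut is an accepted
    # simplification.
    w0 = shoulder + start
    w1 = shoulder + start + params.amplitude_fraction * (end - start)
    e0 = _two_link_elbow(shoulder, w0)
    e1 = _two_link_elbow(shoulder, w1)
    h0 = w0 + HAND_OFFSET * (w0 - e0) / np.linalg.norm(w0 - e0)
    h1 = w1 + HAND_OFFSET * (w1 - e1) / np.linalg.norm(w1 - e1)
    wrist = w0 + np.outer(profile, w1 - w0)
    elbow = e0 + np.outer(profile, e1 - e0)
    hand = h0 + np.outer(profile, h1 - h0)

    if params.tremor_amplitude > 0:
        # intention-type tremor: strongest mid-movement, absent at rest
        vel = 30 * tau**2 * (1 - tau) ** 2
        env = np.concatenate([np.zeros(n_pad), vel / 1.875, np.zeros(n_pad)])
        tremor = params.tremor_amplitude * _band_limited_noise(n, fs, params.tremor_band, rng)
        tremor = tremor * env[:, None]
        hand = hand + tremor
        wrist = wrist + 0.8 * tremor
        elbow = elbow + 0.4 * tremor

    # static opposite arm hanging at rest
    o_elbow = other_shoulder + np.array([0.0, -UPPER_ARM, 0.02])
    o_wrist = o_elbow + np.array([0.0, -FOREARM, 0.02])
    o_hand = o_wrist + np.array([0.0, -HAND_OFFSET, 0.0])

    xyz = np.empty((n, len(JOINTS), 3))
    s = params.side[0]
    o = "r" if s == "l" else "l"
    static = {
        "head": HEAD,
        "shoulder_center": SHOULDER_CENTER,
        f"shoulder_{s}": shoulder,
        f"shoulder_{o}": other_shoulder,
        f"elbow_{o}": o_elbow,
        f"wrist_{o}": o_wrist,
        f"hand_{o}": o_hand,
    }
    for name, pos in static.items():
        xyz[:, JOINT_INDEX[name], :] = pos
    xyz[:, JOINT_INDEX[f"elbow_{s}"], :] = elbow
    xyz[:, JOINT_INDEX[f"wrist_{s}"], :] = wrist
    xyz[:, JOINT_INDEX[f"hand_{s}"], :] = hand

    # Sensor error of an SDK-smoothed skeleton stream: joint estimates wander
    # slowly (drift, strongest error component but spectrally far below any
    # movement content) with a small broadband jitter residue on top.
    if params.sensor_drift_sd > 0:
        b, a = butter(2, 0.3 / (fs / 2.0), btype="low")
        drift = filtfilt(b, a, rng.standard_normal((n + 128, xyz.shape[1] * 3)), axis=0)[:n]
        rms = np.sqrt(np.mean(drift**2, axis=0))
        drift = params.sensor_drift_sd * drift / np.maximum(rms, 1e-12)
        xyz = xyz + drift.reshape(n, xyz.shape[1], 3)
    if params.sensor_noise_sd > 0:
        xyz = xyz + rng.normal(0.0, params.sensor_noise_sd, xyz.shape)

    t = np.arange(n) / fs
    return MotionRecording(
        subject_id=params.subject_id,
        side=params.side,
        item=params.item,
        frame_rate=fs,
        t=t,
        xyz=xyz,
    )


def sample_class_params(
    item: FMAItem,
    score_class: int,
    rng: np.random.Generator,
    stage: int | None = None,
    tremor_by_stage: dict[int, float] | None = None,
    side: str = "left",
    subject_id: str = "synth",
) -> MotionParams:
    """Draw attempt parameters for one generative score class.

    Amplitude is uniform in the class band; tempo slows with impairment;
    tremor follows the Brunnstrom stage (defaults to a stage consistent with
    the class when not given).
    """
    tremor_by_stage = tremor_by_stage or DEFAULT_TREMOR_BY_STAGE
    if stage is None:
        stage = {0: 2, 1: 4, 2: 6}[score_class]
    lo, hi = CLASS_AMPLITUDE[score_class]
    return MotionParams(
        item=item,
        score_class=score_class,
        amplitude_fraction=float(rng.uniform(lo, hi)),
        duration=float(2.0 + 0.5 * (2 - score_class) + rng.uniform(-0.2, 0.2)),
        tremor_amplitude=float(tremor_by_stage[stage]),
        seed=int(rng.integers(2**31)),
        side=side,
        subject_id=subject_id,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort: recordings keyed by (subject, side, item) + table."""

    recordings: dict[tuple[str, str, str], MotionRecording]
    table: CohortTable

    def recording(self, subject_id: str, side: str, item: FMAItem) -> MotionRecording:
        return self.recordings[(subject_id, side, item.value)]


def synth_cohort(
    n_per_item_and_class: int,
    item_set: list[FMAItem] | None = None,
    jerk_severity_by_stage: dict[int, float] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a paired bilateral cohort with known generative labels.

    For each score class, ``n_per_item_and_class`` subjects are created whose
    hemiplegic side performs every item at that class (so the requested
    per-item-and-class counts hold exactly) and whose non-hemiplegic side
    performs at full amplitude with minimal tremor.  The Brunnstrom stage
    alternates within the class (class 0 -> stages 1/2, class 1 -> 3/4,
    class 2 -> 5/6) and drives the tremor amplitude inversely, so the cohort
    reproduces, by construction, a higher hemiplegic jerk score and a
    negative stage-smoothness correlation.
    """
    if n_per_item_and_class < 1:
        raise ValidationError("n_per_item_and_class must be >= 1")
    items = item_set or list(FMAItem)
    tremor_by_stage = jerk_severity_by_stage or DEFAULT_TREMOR_BY_STAGE
    rng = np.random.default_rng(seed)
    stage_for_class = {0: (1, 2), 1: (3, 4), 2: (5, 6)}

    recordings: dict[tuple[str, str, str], MotionRecording] = {}
    rows = []
    idx = 0
    for score_class in (0, 1, 2):
        for k in range(n_per_item_and_class):
            subject = f"S{idx:04d}"
            idx += 1
            stage = stage_for_class[score_class][k % 2]
            hemi_side = "left" if idx % 2 else "right"
            other_side = "right" if hemi_side == "left" else "left"
            item_scores = {item.value: score_class for item in items}
            sum_13 = score_class * len(list(FMAItem))
            total = int(np.clip(33 * score_class + rng.integers(-3, 4), sum_13, MAX_UE_TOTAL))
            for side, hemiplegic in ((hemi_side, True), (other_side, False)):
                for item in items:
                    if hemiplegic:
                        params = sample_class_params(
                            item, score_class, rng, stage=stage,
                            tremor_by_stage=tremor_by_stage,
                            side=side, subject_id=subject,
                        )
                    else:
                        lo, hi = CLASS_AMPLITUDE[2]
                        params = MotionParams(
                            item=item,
                            score_class=2,
                            amplitude_fraction=float(rng.uniform(lo, hi)),
                            duration=float(2.0 + rng.uniform(-0.2, 0.2)),
                            tremor_amplitude=HEALTHY_TREMOR,
                            seed=int(rng.integers(2**31)),
                            side=side,
                            subject_id=subject,
                        )
                    recordings[(subject, side, item.value)] = synth_motion(params)
                row = {
                    "subject_id": subject,
                    "side": side,
                    "hemiplegic": hemiplegic,
                    "brunnstrom_arm": stage if hemiplegic else 6,
                    "sum_13": sum_13 if hemiplegic else 26,
                    "total_66": total if hemiplegic else MAX_UE_TOTAL,
                }
                for item_enum in FMAItem:
                    row[item_enum.value] = score_class if hemiplegic else 2
                rows.append(row)
    table = CohortTable(df=pd.DataFrame(rows))
    return SyntheticCohort(recordings=recordings, table=table)
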