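"""Data model and file I/O for skeletal motion recordings and cohort score tables.

A recording is a uniform-rate sequence of skeleton frames captured by a
depth-sensing camera while a subject performs one Fugl-Meyer Assessment (FMA)
item.  Each frame carries a timestamp plus ten upper-body joints in 3-D camera
coordinates (x lateral, y vertical, z depth), i.e. 1 + 10 x 3 = 31 scalar
values per frame.  Files are plain delimited text, one frame per row, with
optional ``#``-prefixed metadata header lines.

A cohort table holds, per subject and side, the therapist's per-item scores
(0/1/2 for each of the 13 camera-recorded items), the 13-item sum (0-26), the
full 33-item upper-extremity total (0-66), the Brunnstrom arm stage (1-6) and
a hemiplegic-side flag.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

#: Canonical joint order used on disk and in memory.
JOINTS: tuple[str, ...] = (
    "head",
    "shoulder_center",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "hand_l",
    "hand_r",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINTS)}

#: time + 10 joints x 3 coordinates
N_COLUMNS = 1 + 3 * len(JOINTS)


class FMAItem(Enum):
    """The 13 upper-extremity FMA motor items assessed from camera motion data.

    Six flexor-synergy items, three extensor-synergy items, two mixed-synergy
    items and two low-synergy volitional items.  Every item is scored 0
    (cannot perform), 1 (partial) or 2 (full), so each carries a maximum
    score of 2.
    """

    SHOULDER_RETRACTION = "shoulder_retraction"
    SHOULDER_ELEVATION = "shoulder_elevation"
    SHOULDER_ABDUCTION = "shoulder_abduction"
    SHOULDER_EXTERNAL_ROTATION = "shoulder_external_rotation"
    ELBOW_FLEXION = "elbow_flexion"
    FOREARM_SUPINATION = "forearm_supination"
    SHOULDER_ADDUCTION_INTERNAL_ROTATION = "shoulder_adduction_internal_rotation"
    ELBOW_EXTENSION = "elbow_extension"
    FOREARM_PRONATION = "forearm_pronation"
    HAND_TO_LUMBAR_SPINE = "hand_to_lumbar_spine"
    SHOULDER_FLEXION_0_90 = "shoulder_flexion_0_90"
    SHOULDER_ABDUCTION_0_90 = "shoulder_abduction_0_90"
    SHOULDER_FLEXION_90_180 = "shoulder_flexion_90_180"

    @property
    def max_score(self) -> int:
        return 2

    @classmethod
    def from_string(cls, s: str) -> "FMAItem":
        key = s.strip().lower()
        for item in cls:
            if item.value == key or item.name.lower() == key:
                return item
        raise ValidationError(f"unknown FMA item: {s!r}")


#: Number of implemented items and the maximal 13-item sum.
N_ITEMS = len(FMAItem)
MAX_ITEM_SUM = 2 * N_ITEMS  # 26
#: Full upper-extremity motor domain total (33 items).
MAX_UE_TOTAL = 66

SIDES = ("left", "right")


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped skeleton sample: 31 scalar values."""

    t: float
    joints: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if set(self.joints) != set(JOINTS):
            raise ValidationError(
                f"frame must contain exactly the {len(JOINTS)} canonical joints"
            )
        vals = [self.t, *(c for p in self.joints.values() for c in p)]
        if not np.all(np.isfinite(vals)):
            raise ValidationError("frame contains non-finite values")


@dataclass
class Dialect:
    """On-disk layout of a recording file.

    The camera vendor never fixed a public text layout, so the column order,
    delimiter and units are declared here and can be loaded from a YAML/JSON
    config.  Defaults: time first, then joints in :data:`JOINTS` order, each
    as x,y,z; whitespace/comma auto-detected; meters and seconds.
    """

    delimiter: str | None = None  # None = auto-detect (comma vs whitespace)
    joint_order: tuple[str, ...] = JOINTS
    position_units: str = "m"  # "m" or "mm"
    time_units: str = "s"  # "s" or "ms"

    def position_scale(self) -> float:
        return {"m": 1.0, "mm": 1e-3}[self.position_units]

    def time_scale(self) -> float:
        return {"s": 1.0, "ms": 1e-3}[self.time_units]

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "joint_order" in data:
            data["joint_order"] = tuple(data["joint_order"])
        return cls(**data)


@dataclass
class MotionRecording:
    """One FMA item attempt: timestamps, joint positions and metadata.

    ``xyz`` has shape ``(n_frames, 10, 3)`` with joints in :data:`JOINTS`
    order; positions are meters (or dimensionless after pose normalization),
    timestamps are seconds and strictly increasing.
    """

    subject_id: str
    side: str
    item: FMAItem
    frame_rate: float
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if not isinstance(self.item, FMAItem):
            raise ValidationError("item must be an FMAItem")
        if self.frame_rate <= 0:
            raise ValidationError("frame rate must be positive")
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValidationError("a recording needs at least 2 frames")
        if self.xyz.shape != (self.t.size, len(JOINTS), 3):
            raise ValidationError(
                f"xyz must have shape (n, {len(JOINTS)}, 3), got {self.xyz.shape}"
            )
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.xyz))):
            raise ValidationError("recording contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def joint(self, name: str) -> np.ndarray:
        """Positions of one joint over time, shape ``(n_frames, 3)``."""
        return self.xyz[:, JOINT_INDEX[name], :]

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            t=float(self.t[i]),
            joints={name: tuple(self.xyz[i, j]) for name, j in JOINT_INDEX.items()},
        )

    @property
    def frames(self) -> list[SkeletonFrame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def copy(self, **changes) -> "MotionRecording":
        rec = replace(self, **changes)
        rec.t = rec.t.copy()
        rec.xyz = rec.xyz.copy()
        return rec


_META_RE = re.compile(r"^#\s*(\w+)\s*=\s*(.+?)\s*$")


def _metadata_from_filename(path: Path) -> dict[str, str]:
    # fallback convention: <subject>_<side>_<item>.<ext>
    parts = path.stem.split("_")
    if len(parts) >= 3 and parts[1] in SIDES:
        return {
            "subject": parts[0],
            "side": parts[1],
            "item": "_".join(parts[2:]),
        }
    return {}


def read_recording(
    path: str | Path, dialect: Dialect | None = None
) -> MotionRecording:
    """Read one delimited-text recording (31 numeric columns per row).

    Metadata (subject, side, item, frame rate) is taken from ``#`` header
    lines (``subject=``, ``side=``, ``item=``, ``frame_rate=``) or, failing
    that, from a ``<subject>_<side>_<item>`` filename.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    meta: dict[str, str] = _metadata_from_filename(path)
    rows: list[list[float]] = []
    times: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _META_RE.match(line)
            if m:
                meta[m.group(1).lower()] = m.group(2)
                continue
            if line.startswith("#"):
                continue
            delim = dialect.delimiter or ("," if "," in line else None)
            fields = [f for f in line.split(delim) if f != ""]
            if len(fields) != N_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {N_COLUMNS} fields, got {len(fields)}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            times.append(values[0])
            rows.append(values[1:])
    if not rows:
        raise ParseError(f"{path}: no data rows (0 frames)")

    order = dialect.joint_order
    perm = [order.index(j) for j in JOINTS]
    xyz = np.asarray(rows, dtype=float).reshape(len(rows), len(JOINTS), 3)
    xyz = xyz[:, perm, :] * dialect.position_scale()
    t = np.asarray(times, dtype=float) * dialect.time_scale()

    try:
        item = FMAItem.from_string(meta["item"])
    except KeyError:
        raise ParseError(f"{path}: no item metadata in header or filename") from None
    return MotionRecording(
        subject_id=meta.get("subject", path.stem),
        side=meta.get("side", "left"),
        item=item,
        frame_rate=float(meta.get("frame_rate", 30.0)),
        t=t,
        xyz=xyz,
    )


def write_recording(
    rec: MotionRecording, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write the 31-column delimited text format (lossless round trip)."""
    rec.validate()
    path = Path(path)
    dialect = dialect or Dialect()
    delim = dialect.delimiter or " "
    perm = [JOINT_INDEX[j] for j in dialect.joint_order]
    pscale = dialect.position_scale()
    tscale = dialect.time_scale()
    with path.open("w") as fh:
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# side={rec.side}\n")
        fh.write(f"# item={rec.item.value}\n")
        fh.write(f"# frame_rate={rec.frame_rate:.17g}\n")
        for i in range(rec.n_frames):
            vals = [rec.t[i] / tscale]
            vals.extend((rec.xyz[i, perm, :] / pscale).ravel())
            fh.write(delim.join(f"{v:.17g}" for v in vals) + "\n")


# ---------------------------------------------------------------------------
# Cohort score tables
# ---------------------------------------------------------------------------

#: Default column names expected in cohort CSV/XLSX files.
COHORT_COLUMNS = {
    "subject_id": "subject_id",
    "side": "side",
    "hemiplegic": "hemiplegic",
    "brunnstrom_arm": "brunnstrom_arm",
    "sum_13": "sum_13",  # optional; recomputed from item columns
    "total_66": "total_66",
}

ITEM_COLUMNS = {item: item.value for item in FMAItem}


@dataclass
class CohortTable:
    """Per subject-and-side therapist scores, stages and totals.

    Backed by a pandas DataFrame with canonical column names; ``issues``
    lists human-readable descriptions of rows that violate invariants (such
    rows are flagged, never silently dropped).
    """

    df: pd.DataFrame
    issues: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def hemiplegic_rows(self) -> pd.DataFrame:
        return self.df[self.df["hemiplegic"].astype(bool)]

    def item_scores(self, row: pd.Series) -> list[int]:
        return [int(row[item.value]) for item in FMAItem]


def validate_cohort_frame(df: pd.DataFrame) -> list[str]:
    """Return invariant violations, one message per offending cell/row."""
    issues: list[str] = []
    for idx, row in df.iterrows():
        for item in FMAItem:
            v = row[item.value]
            if v not in (0, 1, 2):
                issues.append(f"row {idx}: {item.value} score {v!r} not in {{0,1,2}}")
        s = row.get("sum_13")
        recomputed = sum(int(row[i.value]) for i in FMAItem if row[i.value] in (0, 1, 2))
        if pd.notna(s) and int(s) != recomputed:
            issues.append(f"row {idx}: stored sum_13={s} != recomputed {recomputed}")
        total = row.get("total_66")
        if pd.notna(total) and not (0 <= int(total) <= MAX_UE_TOTAL):
            issues.append(f"row {idx}: total_66={total} outside [0, {MAX_UE_TOTAL}]")
        stage = row.get("brunnstrom_arm")
        if pd.notna(stage) and int(stage) not in range(1, 7):
            issues.append(f"row {idx}: brunnstrom_arm={stage} outside 1..6")
        if row.get("side") not in SIDES:
            issues.append(f"row {idx}: side={row.get('side')!r} not in {SIDES}")
    return issues


def read_cohort(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> CohortTable:
    """Read a cohort score table from CSV or XLSX.

    ``column_map`` maps canonical names (``subject_id``, ``side``,
    ``hemiplegic``, ``brunnstrom_arm``, item names, optional ``sum_13`` /
    ``total_66``) to the file's actual column headers.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})

    mandatory = ["subject_id", "side", "brunnstrom_arm"] + [i.value for i in FMAItem]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {', '.join(missing)}")
    if "hemiplegic" not in df.columns:
        df["hemiplegic"] = True
    if "sum_13" not in df.columns:
        df["sum_13"] = df[[i.value for i in FMAItem]].sum(axis=1)
    issues = validate_cohort_frame(df)
    return CohortTable(df=df, issues=issues)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.df.to_excel(path, index=False)
    else:
        table.df.to_csv(path, index=False)
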