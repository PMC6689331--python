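"""Core data model for 3D joint-center trajectories and their file formats.

A trial is a time series of labelled joint-center positions for the left and
right hip, knee, ankle, and toe, recorded by one capture system at a fixed
sampling rate.  All internal computation is in metres with an explicit
vertical axis; downstream reporting converts to degrees, millimetres,
centimetres, or ratios as each variable requires.

The on-disk CSV dialect is plain text: ``#``-prefixed header lines declare
the sampling rate, units, and vertical axis, followed by one row per frame
with ``frame, <joint>_x, <joint>_y, <joint>_z`` columns.  The standard TRC
header (DataRate / NumFrames / Units) is also read.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "JOINTS",
    "SIDES",
    "AxisConvention",
    "TrialTrajectory",
    "EventSet",
    "TrialMeta",
    "TrajectoryFormatError",
    "DegenerateGeometryError",
    "read_trajectory",
    "write_trajectory",
    "downsample",
    "project_frontal",
]

#: Required joint labels, in canonical column order.
JOINTS = (
    "hip_L", "hip_R",
    "knee_L", "knee_R",
    "ankle_L", "ankle_R",
    "toe_L", "toe_R",
)

SIDES = ("L", "R")

_AXES = {"x": 0, "y": 1, "z": 2}


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the documented dialect."""


class DegenerateGeometryError(ValueError):
    """A geometric construction is undefined (coincident points etc.)."""


@dataclasses.dataclass(frozen=True)
class AxisConvention:
    """Names which coordinate axis is vertical; the other two span the ground plane."""

    vertical: str = "z"

    def __post_init__(self) -> None:
        if self.vertical not in _AXES:
            raise ValueError(f"vertical axis must be one of {sorted(_AXES)}, got {self.vertical!r}")

    @property
    def vertical_index(self) -> int:
        return _AXES[self.vertical]

    @property
    def ground_indices(self) -> tuple[int, int]:
        return tuple(i for i in range(3) if i != self.vertical_index)  # type: ignore[return-value]


@dataclasses.dataclass
class TrialTrajectory:
    """Labelled 3D joint-center positions for one trial on one system.

    Parameters
    ----------
    joints
        Mapping from joint label (see :data:`JOINTS`) to an ``(n_frames, 3)``
        array of positions in metres.
    rate_hz
        Sampling rate in samples per second.
    axes
        Which axis is vertical; defaults to ``z``.
    """

    subject_id: str
    trial_id: str
    movement: str  # "squat" | "broad_jump"
    system_id: str
    rate_hz: float
    joints: dict[str, np.ndarray]
    axes: AxisConvention = dataclasses.field(default_factory=AxisConvention)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        missing = [j for j in JOINTS if j not in self.joints]
        if missing:
            raise TrajectoryFormatError(f"missing joint column(s): {', '.join(missing)}")
        self.joints = {j: np.asarray(self.joints[j], dtype=float) for j in JOINTS}
        lengths = {a.shape for a in self.joints.values()}
        n = self.n_frames
        if any(a.ndim != 2 or a.shape[1] != 3 for a in self.joints.values()) or len(
            {a.shape[0] for a in self.joints.values()}
        ) != 1:
            raise ValueError(f"all joint series must share shape (n, 3); got {lengths}")
        if n < 2:
            raise ValueError(f"trajectory needs >= 2 frames, got {n}")
        for j, a in self.joints.items():
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite coordinates in joint {j!r}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.joints.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    def vertical(self, joint: str) -> np.ndarray:
        """Height series (metres) of one joint."""
        return self.joints[joint][:, self.axes.vertical_index]

    def ground(self, joint: str) -> np.ndarray:
        """(n, 2) ground-plane coordinates of one joint."""
        return self.joints[joint][:, list(self.axes.ground_indices)]

    def slice(self, start: int, stop: int) -> "TrialTrajectory":
        """Half-open frame slice [start, stop) as a new trajectory."""
        return dataclasses.replace(
            self, joints={j: a[start:stop] for j, a in self.joints.items()}
        )


@dataclasses.dataclass
class EventSet:
    """Trim window plus optional jump events for one trial.

    ``trim_start``/``trim_end`` delimit a half-open window ``[start, end)``
    in 0-based frame indices.  For jumps, ``toe_off`` is the last frame with
    toe-ground contact and ``full_foot_contact`` the first frame after flight
    with one foot flat on the floor.
    """

    trim_start: int
    trim_end: int
    toe_off: int | None = None
    full_foot_contact: int | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.trim_start < self.trim_end:
            raise ValueError(
                f"need 0 <= trim_start < trim_end, got [{self.trim_start}, {self.trim_end})"
            )
        if self.toe_off is not None and self.full_foot_contact is not None:
            if not self.toe_off < self.full_foot_contact:
                raise ValueError("toe_off must precede full_foot_contact")

    def shift(self, k: int) -> "EventSet":
        return EventSet(
            self.trim_start + k,
            self.trim_end + k,
            None if self.toe_off is None else self.toe_off + k,
            None if self.full_foot_contact is None else self.full_foot_contact + k,
            self.warning,
        )


@dataclasses.dataclass(frozen=True)
class TrialMeta:
    subject_id: str
    trial_id: str
    movement: str
    height_cm: float
    age_y: float = float("nan")
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError("height_cm must be positive")


# ---------------------------------------------------------------------------
# CSV dialect


def write_trajectory(traj: TrialTrajectory, path: str | Path, dialect: str = "csv") -> None:
    """Write a trajectory; ``read_trajectory`` round-trips to 1e-9 m."""
    if dialect != "csv":
        raise ValueError(f"only the csv dialect is writable, got {dialect!r}")
    path = Path(path)
    cols: dict[str, np.ndarray] = {"frame": np.arange(traj.n_frames)}
    for j in JOINTS:
        for k, ax in enumerate("xyz"):
            cols[f"{j}_{ax}"] = traj.joints[j][:, k]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={traj.rate_hz!r}\n")
        fh.write("# units=m\n")
        fh.write(f"# vertical_axis={traj.axes.vertical}\n")
        fh.write(f"# subject_id={traj.subject_id}\n")
        fh.write(f"# trial_id={traj.trial_id}\n")
        fh.write(f"# movement={traj.movement}\n")
        fh.write(f"# system_id={traj.system_id}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path: str | Path, dialect: str = "csv") -> TrialTrajectory:
    """Read a trajectory file in the csv or trc dialect.

    Positions are converted to metres per the declared units.  A missing
    joint column or a non-monotone frame/time column raises
    :class:`TrajectoryFormatError` naming the offender.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "trc":
        return _read_trc(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> TrialTrajectory:
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    if "rate_hz" not in header:
        raise TrajectoryFormatError(f"{path}: header lacks rate_hz")
    rate = float(header["rate_hz"])
    units = header.get("units", "m")
    scale = {"m": 1.0, "mm": 1e-3}.get(units)
    if scale is None:
        raise TrajectoryFormatError(f"{path}: unknown units {units!r}")
    df = pd.read_csv(_io.StringIO("".join(body_lines)))
    if "frame" in df.columns and not np.all(np.diff(df["frame"].to_numpy()) > 0):
        raise TrajectoryFormatError(f"{path}: non-monotone frame column")
    joints: dict[str, np.ndarray] = {}
    for j in JOINTS:
        cols = [f"{j}_{ax}" for ax in "xyz"]
        if any(c not in df.columns for c in cols):
            raise TrajectoryFormatError(f"{path}: missing joint column for {j!r}")
        joints[j] = df[cols].to_numpy(dtype=float) * scale
    return TrialTrajectory(
        subject_id=header.get("subject_id", "?"),
        trial_id=header.get("trial_id", "?"),
        movement=header.get("movement", "squat"),
        system_id=header.get("system_id", "?"),
        rate_hz=rate,
        joints=joints,
        axes=AxisConvention(header.get("vertical_axis", "z")),
    )


def _read_trc(path: Path) -> TrialTrajectory:
    # TRC layout: line 1 file id, line 2 header keys, line 3 header values,
    # line 4 marker names (one per 3 coordinate columns), line 5 X1 Y1 Z1 ...,
    # then (optionally after a blank line) frame rows: Frame# Time X Y Z ...
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise TrajectoryFormatError(f"{path}: truncated TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    hdr = dict(zip(keys, vals))
    try:
        rate = float(hdr["DataRate"])
        units = hdr["Units"].strip()
    except KeyError as exc:
        raise TrajectoryFormatError(f"{path}: TRC header lacks {exc}") from exc
    scale = {"m": 1.0, "mm": 1e-3}.get(units)
    if scale is None:
        raise TrajectoryFormatError(f"{path}: unknown TRC units {units!r}")
    marker_row = lines[3].split("\t")
    markers = [m.strip() for m in marker_row[2:] if m.strip()]
    data_rows = [
        ln.split("\t") for ln in lines[5:] if ln.strip() and not ln.startswith("X1")
    ]
    arr = np.array([[float(v) for v in row if v.strip() != ""] for row in data_rows])
    times = arr[:, 1]
    if not np.all(np.diff(times) > 0):
        raise TrajectoryFormatError(f"{path}: non-monotone time column")
    joints: dict[str, np.ndarray] = {}
    for i, m in enumerate(markers):
        joints[m] = arr[:, 2 + 3 * i : 5 + 3 * i] * scale
    missing = [j for j in JOINTS if j not in joints]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing joint column for {missing[0]!r}")
    return TrialTrajectory(
        subject_id="?", trial_id="?", movement="squat", system_id="?",
        rate_hz=rate, joints={j: joints[j] for j in JOINTS},
    )


# ---------------------------------------------------------------------------
# Resampling and frontal-plane projection


def downsample(traj: TrialTrajectory, target_hz: float) -> TrialTrajectory:
    """Decimate to ``target_hz`` keeping every (rate/target)-th frame from 0.

    Pure decimation, no anti-alias filtering: retained samples are
    bit-identical to the input.  The rate ratio must be an integer.
    """
    ratio = traj.rate_hz / target_hz
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"rate {traj.rate_hz} Hz is not an integer multiple of target {target_hz} Hz"
        )
    if factor == 1:
        return dataclasses.replace(traj, joints={j: a.copy() for j, a in traj.joints.items()})
    return dataclasses.replace(
        traj,
        rate_hz=float(target_hz),
        joints={j: a[::factor].copy() for j, a in traj.joints.items()},
    )


def project_frontal(
    traj: TrialTrajectory, frame: int
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Project all joints of one frame onto the subject's frontal plane.

    The frontal plane is re-derived per frame: its medio-lateral (ML) axis is
    the unit hip_L -> hip_R direction projected into the ground plane, its
    second axis is vertical, and its origin is the midpoint of the two hip
    centers.  Anterior-posterior displacement is discarded.

    Returns
    -------
    points
        joint label -> ``(ml, vertical)`` 2D coordinates in metres.
    medial_sign
        side -> sign (+1/-1) such that ``medial_sign[side] * ml`` increases
        toward that leg's medial direction (toward the contralateral hip).
    """
    g = traj.axes.ground_indices
    v = traj.axes.vertical_index
    hip_l = traj.joints["hip_L"][frame]
    hip_r = traj.joints["hip_R"][frame]
    ml3 = hip_r[list(g)] - hip_l[list(g)]
    norm = float(np.linalg.norm(ml3))
    if norm < 1e-12:
        raise DegenerateGeometryError(
            f"hip centers coincident in the ground plane at frame {frame}"
        )
    ml_axis = ml3 / norm
    origin_g = (hip_l[list(g)] + hip_r[list(g)]) / 2.0
    origin_v = (hip_l[v] + hip_r[v]) / 2.0
    points: dict[str, np.ndarray] = {}
    for j in JOINTS:
        p = traj.joints[j][frame]
        ml = float(np.dot(p[list(g)] - origin_g, ml_axis))
        points[j] = np.array([ml, p[v] - origin_v])
    # Left leg's medial direction points toward the right hip, i.e. +ML.
    return points, {"L": 1.0, "R": -1.0}
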