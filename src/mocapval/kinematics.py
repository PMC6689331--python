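"""Per-frame kinematic and performance variables from joint-center positions.

Planar frontal-plane measures (FPKA, FPPA, FPKD) operate on 2D points in the
subject's frontal plane as produced by :func:`mocapval.trajectory.project_frontal`:
first axis medio-lateral, second vertical.  Sign conventions are mirrored
across sides so that left and right legs are directly comparable:

* FPKA: ankle medial to the knee is positive.
* FPPA: knee medial to the hip-ankle line (valgus) is positive.
* FPKD: millimetres, knee medial to the hip-ankle line is *negative*
  (so FPPA and -FPKD agree in sign).
* knee varus proxy: knee lateral is positive (the negative of FPPA's sense).

Separation-distance ratios (KHR, AHR) are 3D inter-joint distances divided by
the inter-hip distance, hence dimensionless and scale-invariant.

Sagittal angles (hip/knee flexion, ankle dorsiflexion) are joint-center
proxies: they use only the eight joint centers, not a full marker-set
biomechanical model, and are applied identically to both systems.

All signed angles are built from atan2 constructions, never bare arccos, so
values near 0 deg and 180 deg remain stable; ranges are (-180, 180].
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .trajectory import (
    DegenerateGeometryError,
    EventSet,
    TrialTrajectory,
)

__all__ = [
    "KinematicSeries",
    "JumpMetrics",
    "VARIABLES",
    "fpka",
    "fppa",
    "fpkd",
    "khr",
    "ahr",
    "sagittal_angles",
    "knee_varus_proxy",
    "jump_length",
    "jump_height",
    "frontal_coords",
    "compute_series",
]

#: variable name -> units
VARIABLES = {
    "knee_flexion": "deg",
    "hip_flexion": "deg",
    "ankle_dorsiflexion": "deg",
    "knee_varus": "deg",
    "fppa": "deg",
    "fpka": "deg",
    "fpkd": "mm",
    "khr": "ratio",
    "ahr": "ratio",
}

BILATERAL = ("khr", "ahr")


@dataclasses.dataclass
class KinematicSeries:
    """Per-frame values of one named variable for one trial/system/side."""

    variable: str
    side: str  # "L" | "R" | "bilateral"
    values: np.ndarray
    units: str
    subject_id: str = "?"
    trial_id: str = "?"
    system_id: str = "?"
    movement: str = "?"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        expect_bilateral = self.variable in BILATERAL
        if (self.side == "bilateral") != expect_bilateral:
            raise ValueError(f"{self.variable} side must {'be' if expect_bilateral else 'not be'} bilateral")


@dataclasses.dataclass(frozen=True)
class JumpMetrics:
    jump_length_cm: float
    jump_height_cm: float  # negative if descent began before toe-off


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def _check_sep(p: np.ndarray, q: np.ndarray, what: str) -> None:
    if np.any(np.linalg.norm(np.atleast_2d(q - p), axis=-1) < 1e-12):
        raise DegenerateGeometryError(f"coincident points: {what}")


# ---------------------------------------------------------------------------
# Planar frontal-plane measures (2D inputs: [ml, vertical])


def _medial_sign(side: str) -> float:
    if side == "L":
        return 1.0
    if side == "R":
        return -1.0
    raise ValueError(f"side must be 'L' or 'R', got {side!r}")


def fpka(knee2d: np.ndarray, ankle2d: np.ndarray, side: str) -> float | np.ndarray:
    """Frontal-plane knee angle: shank direction vs. straight down, degrees.

    Zero for a vertical shank; positive when the ankle lies medial to the
    knee for the given side.
    """
    knee2d = np.asarray(knee2d, float)
    ankle2d = np.asarray(ankle2d, float)
    _check_sep(knee2d, ankle2d, "knee and ankle in the frontal plane")
    s = _medial_sign(side)
    d = ankle2d - knee2d
    ang = np.degrees(np.arctan2(s * d[..., 0], -d[..., 1]))
    out = _wrap_deg(ang)
    return float(out) if np.ndim(out) == 0 else out


def fppa(
    hip2d: np.ndarray, knee2d: np.ndarray, ankle2d: np.ndarray, side: str
) -> float | np.ndarray:
    """Frontal-plane projection angle: thigh vs. shank direction, degrees.

    Signed angle from unit(hip->knee) to unit(knee->ankle); collinear
    segments give 0.  Valgus (knee medial to the hip-ankle line) is positive
    on both sides after mirroring.
    """
    hip2d, knee2d, ankle2d = (np.asarray(p, float) for p in (hip2d, knee2d, ankle2d))
    _check_sep(hip2d, knee2d, "hip and knee in the frontal plane")
    _check_sep(knee2d, ankle2d, "knee and ankle in the frontal plane")
    s = _medial_sign(side)
    u = knee2d - hip2d
    w = ankle2d - knee2d
    # mirror ML into medial-positive coordinates, then valgus = -cross sense
    cross = s * (u[..., 0] * w[..., 1] - u[..., 1] * w[..., 0])
    dot = u[..., 0] * w[..., 0] + u[..., 1] * w[..., 1]
    out = _wrap_deg(np.degrees(np.arctan2(-cross, dot)))
    return float(out) if np.ndim(out) == 0 else out


def fpkd(
    hip2d: np.ndarray, knee2d: np.ndarray, ankle2d: np.ndarray, side: str
) -> float | np.ndarray:
    """Frontal-plane knee deviation: knee-to-(hip-ankle-line) distance, mm.

    Negative when the knee lies medial to the hip-ankle line.
    """
    hip2d, knee2d, ankle2d = (np.asarray(p, float) for p in (hip2d, knee2d, ankle2d))
    _check_sep(hip2d, ankle2d, "hip and ankle in the frontal plane")
    s = _medial_sign(side)
    d = ankle2d - hip2d
    e = knee2d - hip2d
    cross = s * (d[..., 0] * e[..., 1] - d[..., 1] * e[..., 0])
    out = -cross / np.linalg.norm(d, axis=-1) * 1000.0
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Separation-distance ratios (3D)


def _sep_ratio(traj: TrialTrajectory, frame: int | slice, pair: str) -> float | np.ndarray:
    hips = traj.joints["hip_R"][frame] - traj.joints["hip_L"][frame]
    hip_sep = np.linalg.norm(np.atleast_2d(hips), axis=-1)
    if np.any(hip_sep < 1e-12):
        raise DegenerateGeometryError("zero hip separation")
    other = traj.joints[f"{pair}_R"][frame] - traj.joints[f"{pair}_L"][frame]
    out = np.linalg.norm(np.atleast_2d(other), axis=-1) / hip_sep
    return float(out[0]) if np.isscalar(frame) or isinstance(frame, int) else out


def khr(traj: TrialTrajectory, frame: int | slice) -> float | np.ndarray:
    """Knee-to-hip separation distance ratio (3D, dimensionless)."""
    return _sep_ratio(traj, frame, "knee")


def ahr(traj: TrialTrajectory, frame: int | slice) -> float | np.ndarray:
    """Ankle-to-hip separation distance ratio (3D, dimensionless)."""
    return _sep_ratio(traj, frame, "ankle")


# ---------------------------------------------------------------------------
# Sagittal-plane and varus proxies


def _frame_basis(traj: TrialTrajectory, frame: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (ml, ap, up) orthonormal basis; ap oriented toe-forward."""
    g = list(traj.axes.ground_indices)
    v = traj.axes.vertical_index
    up = np.zeros(3)
    up[v] = 1.0
    ml3 = traj.joints["hip_R"][frame] - traj.joints["hip_L"][frame]
    ml3 = ml3 - np.dot(ml3, up) * up
    n = np.linalg.norm(ml3)
    if n < 1e-12:
        raise DegenerateGeometryError(f"hip centers coincident in ground plane at frame {frame}")
    ml = ml3 / n
    ap = np.cross(up, ml)
    foot = (
        traj.joints["toe_L"][frame] - traj.joints["ankle_L"][frame]
        + traj.joints["toe_R"][frame] - traj.joints["ankle_R"][frame]
    )
    if np.dot(foot, ap) < 0:
        ap = -ap
    return ml, ap, up


def sagittal_angles(
    traj: TrialTrajectory, frame: int, side: str
) -> tuple[float, float, float]:
    """(hip_flexion, knee_flexion, ankle_dorsiflexion) in degrees.

    Joint-center proxies: knee flexion is 180 deg minus the interior 3D angle
    at the knee (0 = straight leg); hip flexion is the signed angle of the
    thigh from straight down within the sagittal plane (the plane orthogonal
    to the per-frame medio-lateral axis), flexion (knee anterior) positive;
    ankle dorsiflexion is the 3D shank-foot angle minus 90 deg, dorsiflexion
    positive.
    """
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    hip = traj.joints[f"hip_{side}"][frame]
    knee = traj.joints[f"knee_{side}"][frame]
    ankle = traj.joints[f"ankle_{side}"][frame]
    toe = traj.joints[f"toe_{side}"][frame]
    for p, q, what in ((hip, knee, "hip/knee"), (knee, ankle, "knee/ankle"), (ankle, toe, "ankle/toe")):
        _check_sep(p, q, what)

    def angle3d(u: np.ndarray, w: np.ndarray) -> float:
        return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, w)), np.dot(u, w))))

    knee_flex = 180.0 - angle3d(hip - knee, ankle - knee)

    _, ap, up = _frame_basis(traj, frame)
    thigh = knee - hip
    hip_flex = float(np.degrees(np.arctan2(np.dot(thigh, ap), -np.dot(thigh, up))))

    ankle_dorsi = angle3d(ankle - knee, toe - ankle) - 90.0
    return hip_flex, knee_flex, ankle_dorsi


def knee_varus_proxy(traj: TrialTrajectory, frame: int, side: str) -> float:
    """Frontal-plane component of the knee angle, degrees; varus (lateral) positive.

    Thigh and shank are projected onto the plane spanned by the per-frame
    medio-lateral axis and the vertical; a joint-center proxy for the
    model-based varus of marker systems.
    """
    from .trajectory import project_frontal

    pts, _ = project_frontal(traj, frame)
    hip2, knee2, ankle2 = pts[f"hip_{side}"], pts[f"knee_{side}"], pts[f"ankle_{side}"]
    return -fppa(hip2, knee2, ankle2, side)


# ---------------------------------------------------------------------------
# Jump performance


def _require_events(events: EventSet) -> tuple[int, int]:
    if events.toe_off is None or events.full_foot_contact is None:
        raise ValueError("jump metrics need both toe_off and full_foot_contact events")
    return events.toe_off, events.full_foot_contact


def jump_length(traj: TrialTrajectory, events: EventSet) -> float:
    """Ground-plane jump length in cm.

    Distance from the inter-ankle midpoint at toe-off to the ankle with the
    lowest vertical position at full-foot contact (ties broken toward the
    left ankle), measured in the ground plane.
    """
    toe_off, ffc = _require_events(events)
    start = (traj.ground("ankle_L")[toe_off] + traj.ground("ankle_R")[toe_off]) / 2.0
    low_side = "L" if traj.vertical("ankle_L")[ffc] <= traj.vertical("ankle_R")[ffc] else "R"
    end = traj.ground(f"ankle_{low_side}")[ffc]
    return float(np.linalg.norm(end - start) * 100.0)


def jump_height(traj: TrialTrajectory, events: EventSet) -> float:
    """Hip-rise jump height in cm; negative if descent began before toe-off.

    Highest mean hip height over [toe_off, full_foot_contact] minus the mean
    hip height at toe-off.
    """
    toe_off, ffc = _require_events(events)
    mean_hip = (traj.vertical("hip_L") + traj.vertical("hip_R")) / 2.0
    # apex over the air phase (after toe-off): negative when the hips were
    # already descending at the first airborne frame
    apex = float(np.max(mean_hip[toe_off + 1 : ffc + 1]))
    return (apex - float(mean_hip[toe_off])) * 100.0


# ---------------------------------------------------------------------------
# Series computation


def frontal_coords(traj: TrialTrajectory) -> dict[str, np.ndarray]:
    """Vectorized frontal-plane coordinates: joint -> (n_frames, 2) [ml, up].

    Same per-frame construction as :func:`project_frontal`, applied to the
    whole trial at once.
    """
    g = list(traj.axes.ground_indices)
    v = traj.axes.vertical_index
    hip_l = traj.joints["hip_L"]
    hip_r = traj.joints["hip_R"]
    ml3 = hip_r[:, g] - hip_l[:, g]
    norms = np.linalg.norm(ml3, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("hip centers coincident in the ground plane")
    ml_axis = ml3 / norms[:, None]
    origin_g = (hip_l[:, g] + hip_r[:, g]) / 2.0
    origin_v = (hip_l[:, v] + hip_r[:, v]) / 2.0
    out: dict[str, np.ndarray] = {}
    for j in traj.joints:
        p = traj.joints[j]
        ml = np.einsum("ij,ij->i", p[:, g] - origin_g, ml_axis)
        out[j] = np.column_stack([ml, p[:, v] - origin_v])
    return out


def compute_series(
    traj: TrialTrajectory, variables: list[str] | None = None, side: str = "L"
) -> list[KinematicSeries]:
    """Compute per-frame series of the requested variables for one trial.

    ``side`` applies to the unilateral variables; KHR/AHR are bilateral.
    """
    variables = list(VARIABLES) if variables is None else variables
    keys = dict(
        subject_id=traj.subject_id, trial_id=traj.trial_id,
        system_id=traj.system_id, movement=traj.movement,
    )
    n = traj.n_frames
    need_frontal = any(v in ("fppa", "fpka", "fpkd", "knee_varus") for v in variables)
    if need_frontal:
        f2 = frontal_coords(traj)
        hip2 = f2[f"hip_{side}"]
        knee2 = f2[f"knee_{side}"]
        ankle2 = f2[f"ankle_{side}"]
    sagittal_vars = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")
    sag = None
    if any(v in sagittal_vars for v in variables):
        sag = np.array([sagittal_angles(traj, i, side) for i in range(n)])
    out: list[KinematicSeries] = []
    for var in variables:
        if var == "khr":
            vals = khr(traj, slice(None))
        elif var == "ahr":
            vals = ahr(traj, slice(None))
        elif var == "fpka":
            vals = fpka(knee2, ankle2, side)
        elif var == "fppa":
            vals = fppa(hip2, knee2, ankle2, side)
        elif var == "fpkd":
            vals = fpkd(hip2, knee2, ankle2, side)
        elif var == "knee_varus":
            vals = -np.asarray(fppa(hip2, knee2, ankle2, side))
        elif var in sagittal_vars:
            vals = sag[:, sagittal_vars.index(var)]
        else:
            raise ValueError(f"unknown variable {var!r}")
        out.append(
            KinematicSeries(
                variable=var,
                side="bilateral" if var in BILATERAL else side,
                values=np.asarray(vals, float),
                units=VARIABLES[var],
                **keys,
            )
        )
    return out
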