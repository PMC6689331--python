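"""Trial trimming, jump-event detection, and measurement extraction.

Trials begin and end with dead time around the actual movement, so squats
are trimmed with an acceleration-based onset detector on the vertical hip
midpoint, and jumps are trimmed from the deepest preparation crouch to the
deepest landing position.  Jump events follow the ground-contact
definitions: toe-off is the last frame where a toe still touches the floor,
full-foot contact the first frame after flight where one foot is flat.

From each per-frame kinematic series we extract peak values (max/min over
the trimmed window), point values (deepest squat, mid-descent, landing
impact, deepest landing), and the through-range vector.  Knee flexion is the
reference clock for every point definition, and point frames are determined
independently per system.

The concrete thresholds (5-SD onset, 3 consecutive frames, 5 mm contact
band, 10 mm flat-foot band, 5th-percentile ground level) are tunable
parameters with these defaults.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import KinematicSeries
from .trajectory import EventSet, TrialTrajectory

__all__ = [
    "MeasurementValue",
    "TrimParams",
    "trim_squat",
    "trim_jump",
    "detect_jump_events",
    "extract_measurements",
    "POINT_TYPES",
]

POINT_TYPES = {
    "squat": ("point_deepest_squat", "point_mid_descent"),
    "broad_jump": ("point_landing_impact", "point_deepest_landing"),
}


@dataclasses.dataclass
class MeasurementValue:
    """One extracted measurement for one trial/system/variable/side."""

    subject_id: str
    trial_id: str
    system_id: str
    movement: str
    variable: str
    side: str
    mtype: str  # max_peak | min_peak | point_* | through_range
    value: float | np.ndarray
    frame: int | None = None


@dataclasses.dataclass(frozen=True)
class TrimParams:
    """Tunable thresholds for the acceleration-based squat trimmer."""

    baseline_s: float = 0.5
    smooth_window_s: float = 0.1
    sd_multiplier: float = 5.0
    min_consecutive: int = 3
    margin_s: float = 0.1
    accel_floor: float = 1e-3  # m/s^2, guards a zero-variance baseline


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.shape[0]]


def _onset_index(accel: np.ndarray, rate_hz: float, p: TrimParams) -> int | None:
    nb = max(2, int(round(p.baseline_s * rate_hz)))
    mu = float(np.mean(accel[:nb]))
    sd = float(np.std(accel[:nb]))
    thr = max(p.sd_multiplier * sd, p.accel_floor)
    exceed = np.abs(accel - mu) > thr
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= p.min_consecutive:
            return i - p.min_consecutive + 1
    return None


def trim_squat(traj: TrialTrajectory, params: TrimParams | None = None) -> EventSet:
    """Trim a squat trial by vertical hip-midpoint acceleration.

    The position is moving-average smoothed, twice centrally differenced,
    and compared against a baseline from the quiet lead-in; onset is the
    first sustained exceedance minus a margin, offset symmetric from the
    reversed series.  If no exceedance is found the full window is returned
    with a warning flag.
    """
    p = params or TrimParams()
    n = traj.n_frames
    dt = 1.0 / traj.rate_hz
    hip_mid = (traj.vertical("hip_L") + traj.vertical("hip_R")) / 2.0
    window = max(1, int(round(p.smooth_window_s * traj.rate_hz)))
    pos = _smooth(hip_mid, window)
    accel = np.gradient(np.gradient(pos, dt), dt)
    margin = int(round(p.margin_s * traj.rate_hz))

    i0 = _onset_index(accel, traj.rate_hz, p)
    if i0 is None:
        return EventSet(0, n, warning="no movement onset detected; full window kept")
    i1 = _onset_index(accel[::-1], traj.rate_hz, p)
    start = max(0, i0 - margin)
    end = n - max(0, (i1 or 0) - margin)
    if end <= start:
        return EventSet(0, n, warning="degenerate trim window; full window kept")
    return EventSet(start, end)


def detect_jump_events(traj: TrialTrajectory, contact_mm: float = 5.0,
                       flat_mm: float = 10.0, ground_pct: float = 5.0,
                       min_flight_frames: int = 3) -> EventSet:
    """Detect toe-off and full-foot contact from foot kinematics.

    Per-foot ground levels are low percentiles of the toe and ankle height
    series.  Contact means a toe within ``contact_mm`` of its ground level;
    toe-off is the last contact frame before the longest no-contact run.
    A foot is flat when both its toe and ankle sit within ``flat_mm`` of
    their own ground levels; full-foot contact is the first flat frame after
    mid-flight (mid-flight, rather than toe-off, anchors the search so that
    near-ground frames immediately after take-off cannot be mistaken for a
    landing).
    """
    n = traj.n_frames
    heights = {j: traj.vertical(j) for j in ("toe_L", "toe_R", "ankle_L", "ankle_R")}
    ground = {j: float(np.percentile(h, ground_pct)) for j, h in heights.items()}
    contact = (heights["toe_L"] < ground["toe_L"] + contact_mm / 1000.0) | (
        heights["toe_R"] < ground["toe_R"] + contact_mm / 1000.0
    )
    # longest run of no-contact frames = flight
    best_len = best_start = 0
    run_start = None
    for i in range(n + 1):
        airborne = i < n and not contact[i]
        if airborne and run_start is None:
            run_start = i
        elif not airborne and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < min_flight_frames or best_start == 0:
        raise ValueError("no jump detected: no flight phase in toe-height series")
    toe_off = best_start - 1

    flat = np.zeros(n, dtype=bool)
    for side in ("L", "R"):
        flat |= (
            heights[f"toe_{side}"] < ground[f"toe_{side}"] + flat_mm / 1000.0
        ) & (heights[f"ankle_{side}"] < ground[f"ankle_{side}"] + flat_mm / 1000.0)
    mid_flight = best_start + best_len // 2
    after = np.flatnonzero(flat[mid_flight:])
    if after.size == 0:
        raise ValueError("no jump detected: no flat-foot frame after flight")
    ffc = int(mid_flight + after[0])
    return EventSet(0, n, toe_off=toe_off, full_foot_contact=ffc)


def trim_jump(knee_flexion: KinematicSeries, events: EventSet) -> EventSet:
    """Trim a jump from the deepest preparation crouch to the deepest landing.

    ``trim_start`` is the knee-flexion argmax before toe-off, ``trim_end``
    one past the knee-flexion argmax from full-foot contact onward.
    """
    if events.toe_off is None or events.full_foot_contact is None:
        raise ValueError("jump trimming needs toe_off and full_foot_contact")
    kf = np.asarray(knee_flexion.values)
    toe_off, ffc = events.toe_off, events.full_foot_contact
    if toe_off < 1:
        raise ValueError("toe_off at frame 0 leaves no preparation phase")
    start = int(np.argmax(kf[:toe_off]))
    end = ffc + int(np.argmax(kf[ffc:])) + 1
    return EventSet(start, end, toe_off=toe_off, full_foot_contact=ffc)


def extract_measurements(
    series: KinematicSeries,
    events: EventSet,
    movement: str,
    knee_flexion: KinematicSeries | None = None,
) -> list[MeasurementValue]:
    """Extract peak, point, and through-range measurements from one series.

    ``knee_flexion`` is the same trial/system's knee-flexion series, the
    reference clock for all point definitions; it defaults to ``series``
    itself (valid only when extracting knee flexion).  Point frames:

    * deepest squat: knee-flexion argmax in the trim window;
    * mid-descent: the pre-argmax frame whose knee flexion is closest to
      half the peak (ties -> earlier frame);
    * landing impact: the full-foot-contact frame;
    * deepest landing: knee-flexion argmax from full-foot contact to the
      trim end.
    """
    kf_series = knee_flexion if knee_flexion is not None else series
    if kf_series.variable != "knee_flexion":
        raise ValueError("the reference clock must be a knee_flexion series")
    lo, hi = events.trim_start, events.trim_end
    vals = np.asarray(series.values)
    kf = np.asarray(kf_series.values)
    if hi <= lo or hi > vals.shape[0]:
        raise ValueError(f"empty or out-of-range trim window [{lo}, {hi})")
    keys = dict(
        subject_id=series.subject_id, trial_id=series.trial_id,
        system_id=series.system_id, movement=movement,
        variable=series.variable, side=series.side,
    )
    win = vals[lo:hi]
    out = [
        MeasurementValue(**keys, mtype="max_peak", value=float(np.max(win)),
                         frame=lo + int(np.argmax(win))),
        MeasurementValue(**keys, mtype="min_peak", value=float(np.min(win)),
                         frame=lo + int(np.argmin(win))),
    ]
    if movement == "squat":
        deepest = lo + int(np.argmax(kf[lo:hi]))
        out.append(MeasurementValue(**keys, mtype="point_deepest_squat",
                                    value=float(vals[deepest]), frame=deepest))
        if deepest > lo:
            descent = kf[lo:deepest]
            mid = lo + int(np.argmin(np.abs(descent - kf[deepest] / 2.0)))
            out.append(MeasurementValue(**keys, mtype="point_mid_descent",
                                        value=float(vals[mid]), frame=mid))
    elif movement == "broad_jump":
        if events.full_foot_contact is None:
            raise ValueError("jump point extraction needs full_foot_contact")
        ffc = events.full_foot_contact
        out.append(MeasurementValue(**keys, mtype="point_landing_impact",
                                    value=float(vals[ffc]), frame=ffc))
        deepest = ffc + int(np.argmax(kf[ffc:hi]))
        out.append(MeasurementValue(**keys, mtype="point_deepest_landing",
                                    value=float(vals[deepest]), frame=deepest))
    else:
        raise ValueError(f"unknown movement {movement!r}")
    out.append(MeasurementValue(**keys, mtype="through_range", value=win.copy()))
    return out
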