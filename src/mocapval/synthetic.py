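"""Synthetic ground-truth squat and standing-broad-jump trajectories.

Emulates the study conditions of a preschool concurrent-validity experiment:
a cohort of 14 children (height mean 109.2 cm, SD 7.9), three trials each of
deep squats and standing broad jumps, observed simultaneously by a reference
marker-based system at 200 Hz and a markerless system at 50 Hz.

The generator produces noise-free ground truth first and then renders
system-specific observations with configurable error models:

* isotropic Gaussian joint-center noise,
* a posterior hip-center bias active near full knee extension (the
  markerless-system failure mode), and
* an impulsive damped medio-lateral knee oscillation after take-off and
  landing ("wand wobble", the marker-system failure mode on jumps).

Movement profiles are smooth cosine-bell splines, not physics simulations:
the statistics under test depend on the error structure, not on dynamic
realism.  Segment lengths follow standard anthropometric fractions of
stature (pelvis width 0.145 h, thigh 0.245 h, shank 0.246 h, foot 0.152 h).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import KinematicSeries, compute_series
from .trajectory import EventSet, JOINTS, TrialTrajectory

__all__ = [
    "SubjectModel",
    "ErrorModel",
    "GroundTruthBundle",
    "generate_cohort",
    "generate_squat_truth",
    "generate_jump_truth",
    "render_observation",
]

GRAVITY = 9.81  # m/s^2

# anthropometric fractions of stature
_PELVIS_F, _THIGH_F, _SHANK_F, _FOOT_F = 0.145, 0.245, 0.246, 0.152
_ANKLE_HEIGHT = 0.05  # m, ankle joint center above ground for a flat foot


@dataclasses.dataclass(frozen=True)
class SubjectModel:
    """Child-scale subject geometry and movement style."""

    subject_id: str
    height_cm: float
    squat_peak_flexion_deg: float = 120.0
    jump_distance_m: float = 0.75
    valgus_tendency_mm: float = 0.0  # medial knee drift at peak flexion

    def __post_init__(self) -> None:
        if not 80.0 <= self.height_cm <= 140.0:
            raise ValueError(f"height_cm outside the child range [80, 140]: {self.height_cm}")
        if not 30.0 < self.squat_peak_flexion_deg <= 160.0:
            raise ValueError("squat peak flexion must lie in (30, 160] deg")
        if not 0.2 < self.jump_distance_m <= 1.3:
            raise ValueError("jump distance must lie in (0.2, 1.3] m")

    @property
    def height_m(self) -> float:
        return self.height_cm / 100.0

    @property
    def pelvis_width_m(self) -> float:
        return _PELVIS_F * self.height_m

    @property
    def thigh_m(self) -> float:
        return _THIGH_F * self.height_m

    @property
    def shank_m(self) -> float:
        return _SHANK_F * self.height_m

    @property
    def foot_m(self) -> float:
        return _FOOT_F * self.height_m


@dataclasses.dataclass(frozen=True)
class ErrorModel:
    """Observation error model for one capture system."""

    system_id: str
    rate_hz: float
    iso_noise_sd_m: float = 0.0
    hip_posterior_bias_m: float = 0.0
    hip_bias_full_ramp_deg: float = 30.0  # bias ramps 1 -> 0 over [0, this] knee flexion
    wobble_amplitude_deg: float = 0.0
    wobble_decay_s: float = 0.25
    wobble_freq_hz: float = 8.0

    def __post_init__(self) -> None:
        if self.iso_noise_sd_m < 0 or self.wobble_amplitude_deg < 0:
            raise ValueError("error SDs and amplitudes must be >= 0")
        if self.wobble_decay_s <= 0:
            raise ValueError("wobble decay must be positive")


@dataclasses.dataclass
class GroundTruthBundle:
    """Noise-free trajectory plus everything needed to score a pipeline run."""

    trajectory: TrialTrajectory
    events: EventSet
    true_series: dict[str, KinematicSeries]
    meta: dict

    @property
    def rate_hz(self) -> float:
        return self.trajectory.rate_hz


def generate_cohort(
    n_subjects: int,
    height_mean_cm: float = 109.2,
    height_sd_cm: float = 7.9,
    seed: int | None = 0,
) -> list[SubjectModel]:
    """Draw a cohort with Normal heights truncated to the child range [80, 140] cm.

    Movement-style parameters (squat depth, jump distance, valgus tendency)
    are drawn per subject from plausible preschool distributions; identical
    seeds give identical cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    heights = np.clip(
        rng.normal(height_mean_cm, height_sd_cm, size=n_subjects), 80.0, 140.0
    )
    peak_flex = np.clip(rng.normal(120.0, 12.0, size=n_subjects), 80.0, 155.0)
    jump_dist = np.clip(rng.normal(0.77, 0.20, size=n_subjects), 0.25, 1.25)
    valgus = np.clip(rng.normal(8.0, 10.0, size=n_subjects), -25.0, 35.0)
    return [
        SubjectModel(
            subject_id=f"S{i + 1:02d}",
            height_cm=float(heights[i]),
            squat_peak_flexion_deg=float(peak_flex[i]),
            jump_distance_m=float(jump_dist[i]),
            valgus_tendency_mm=float(valgus[i]),
        )
        for i in range(n_subjects)
    ]


# ---------------------------------------------------------------------------
# Pose construction


def _pose_frames(
    subject: SubjectModel,
    kf_deg: np.ndarray,
    valgus_scale: np.ndarray,
    ap_shift: np.ndarray,
    up_shift: np.ndarray,
) -> dict[str, np.ndarray]:
    """Joint positions for a symmetric flat-foot pose parameterised by knee flexion.

    Axes: x = medio-lateral (left hip at -x), y = anterior-posterior
    (facing +y), z = vertical.  Knee flexion ``kf`` splits into a forward
    shank tilt (0.4 kf) and a backward thigh tilt (0.6 kf) so the interior
    knee angle is 180 - kf.  ``ap_shift``/``up_shift`` translate the whole
    body (flight phase); ``valgus_scale`` in [0, 1] scales the subject's
    medial knee drift.
    """
    kf = np.radians(kf_deg)
    beta = 0.4 * kf  # shank from vertical, forward
    gamma = 0.6 * kf  # thigh from vertical, backward
    n = kf.shape[0]
    half_w = subject.pelvis_width_m / 2.0
    drift = subject.valgus_tendency_mm / 1000.0 * valgus_scale

    joints: dict[str, np.ndarray] = {}
    for side, sx in (("L", -1.0), ("R", 1.0)):
        ankle = np.zeros((n, 3))
        ankle[:, 0] = sx * half_w
        ankle[:, 2] = _ANKLE_HEIGHT
        knee = ankle.copy()
        knee[:, 1] += subject.shank_m * np.sin(beta)
        knee[:, 2] += subject.shank_m * np.cos(beta)
        # medial drift: toward the contralateral side
        knee[:, 0] -= sx * drift
        hip = knee.copy()
        hip[:, 0] = sx * half_w  # hips unaffected by knee drift
        hip[:, 1] = knee[:, 1] - subject.thigh_m * np.sin(gamma)
        hip[:, 2] = knee[:, 2] + subject.thigh_m * np.cos(gamma)
        toe = ankle.copy()
        toe[:, 1] += subject.foot_m
        toe[:, 2] = 0.0
        for name, arr in (("hip", hip), ("knee", knee), ("ankle", ankle), ("toe", toe)):
            joints[f"{name}_{side}"] = arr
    for j in joints.values():
        j[:, 1] += ap_shift
        j[:, 2] += up_shift
    return joints


def _cos_ramp(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """C1 cosine ramp 0 -> 1 over [t0, t1], clamped outside."""
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _bundle(
    subject: SubjectModel,
    movement: str,
    rate_hz: float,
    joints: dict[str, np.ndarray],
    events: EventSet,
    meta: dict,
) -> GroundTruthBundle:
    traj = TrialTrajectory(
        subject_id=subject.subject_id,
        trial_id=meta.get("trial_id", "T1"),
        movement=movement,
        system_id="truth",
        rate_hz=rate_hz,
        joints=joints,
    )
    series = {s.variable: s for s in compute_series(traj, side="L")}
    return GroundTruthBundle(trajectory=traj, events=events, true_series=series, meta=meta)


def generate_squat_truth(
    subject: SubjectModel,
    duration_s: float = 4.0,
    rate_hz: float = 200.0,
    seed: int | None = 0,
    trial_id: str = "T1",
) -> GroundTruthBundle:
    """One deep squat: quiet stand, C1 descent to peak knee flexion, return.

    The feet stay flat throughout; medial knee drift scales with knee
    flexion per the subject's valgus tendency.  True deepest-squat and
    mid-descent frames are recorded in ``meta``.
    """
    if duration_s < 2.0:
        raise ValueError("squat trials need duration >= 2 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    lead_in = 0.6 + 0.2 * rng.random()  # quiet stand >= 0.5 s
    lead_in = round(lead_in * rate_hz) / rate_hz
    move_T = min(duration_s - lead_in - 0.3, 2.4)
    # snap to an even frame count so the profile peak lands on a sample
    move_T = 2.0 * round(move_T * rate_hz / 2.0) / rate_hz
    peak = subject.squat_peak_flexion_deg
    phase = np.clip((t - lead_in) / move_T, 0.0, 1.0)
    kf = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # 0 -> peak -> 0, C1

    joints = _pose_frames(
        subject, kf, valgus_scale=kf / peak, ap_shift=np.zeros(n), up_shift=np.zeros(n)
    )
    deepest = int(np.argmax(kf))
    descent = kf[:deepest + 1]
    mid_descent = int(np.argmin(np.abs(descent - peak / 2.0)))
    onset = int(round(lead_in * rate_hz))
    end_move = int(round((lead_in + move_T) * rate_hz))
    events = EventSet(trim_start=max(0, onset - 5), trim_end=min(n, end_move + 5))
    meta = {
        "trial_id": trial_id,
        "kf_profile_deg": kf,
        "deepest_frame": deepest,
        "mid_descent_frame": mid_descent,
        "onset_s": lead_in,
        "peak_flexion_deg": peak,
    }
    return _bundle(subject, "squat", rate_hz, joints, events, meta)


def generate_jump_truth(
    subject: SubjectModel,
    rate_hz: float = 200.0,
    seed: int | None = 0,
    trial_id: str = "T1",
) -> GroundTruthBundle:
    """One standing broad jump with an exactly ballistic flight phase.

    Phases: quiet stand, preparation crouch, extension, rigid-pose flight in
    which the whole body translates along a parabola under 9.81 m/s^2, and a
    landing crouch.  The horizontal ankle travel equals the subject's jump
    distance; true toe-off and full-foot-contact frames are recorded.
    """
    rng = np.random.default_rng(seed)
    crouch_kf = 85.0 + 10.0 * rng.random()
    land_kf = 95.0 + 10.0 * rng.random()
    takeoff_kf = 12.0
    t_stand, t_crouch, t_ext = 0.6, 0.55, 0.30
    # flight time scales with jump strength (farther jumpers also rise
    # higher), plus trial-to-trial variation; apex ~ g*T^2/8
    flight_T = float(
        np.clip(0.30 + 0.16 * (subject.jump_distance_m - 0.25) + 0.03 * rng.standard_normal(),
                0.25, 0.55)
    )
    t_land, t_tail = 0.45, 0.45
    duration = t_stand + t_crouch + t_ext + flight_T + t_land + t_tail
    n = int(round(duration * rate_hz))
    t = np.arange(n) / rate_hz

    t1 = t_stand                      # crouch start
    t2 = t1 + t_crouch                # crouch bottom
    t3 = t2 + t_ext                   # take-off
    t4 = t3 + flight_T                # touch-down
    t5 = t4 + t_land                  # deepest landing

    kf = np.select(
        [t < t2, t < t3, t < t4, t < t5],
        [
            crouch_kf * _cos_ramp(t, t1, t2),
            crouch_kf + (takeoff_kf - crouch_kf) * _cos_ramp(t, t2, t3),
            takeoff_kf,  # rigid flight pose
            takeoff_kf + (land_kf - takeoff_kf) * _cos_ramp(t, t4, t5),
        ],
        default=land_kf + (60.0 - land_kf) * _cos_ramp(t, t5, t5 + t_tail),
    )

    # ballistic translation during [t3, t4]: exact parabola, zero elsewhere.
    # The defined jump length runs from the inter-ankle midpoint at toe-off
    # to a single ankle at contact, so the forward travel is shortened by
    # the half-pelvis lateral offset to make that definition equal the
    # subject's jump-distance parameter.
    half_w = subject.pelvis_width_m / 2.0
    ap_travel = float(np.sqrt(max(subject.jump_distance_m**2 - half_w**2, 0.01)))
    tau = np.clip((t - t3) / flight_T, 0.0, 1.0)
    v_z = GRAVITY * flight_T / 2.0
    up_shift = np.where(
        (t >= t3) & (t <= t4),
        v_z * (tau * flight_T) - 0.5 * GRAVITY * (tau * flight_T) ** 2,
        0.0,
    )
    ap_shift = np.where(t >= t3, ap_travel * tau, 0.0)

    joints = _pose_frames(
        subject,
        kf,
        valgus_scale=kf / max(crouch_kf, land_kf),
        ap_shift=ap_shift,
        up_shift=up_shift,
    )

    toe_h = np.minimum(joints["toe_L"][:, 2], joints["toe_R"][:, 2])
    airborne = toe_h > 1e-3
    first_air = int(np.argmax(airborne))
    toe_off = first_air - 1
    grounded_after = (~airborne) & (np.arange(n) > toe_off)
    full_foot = int(np.argmax(grounded_after))
    deepest_landing = int(t5 * rate_hz)
    events = EventSet(
        trim_start=int(np.argmax(kf[:toe_off + 1])),
        trim_end=min(n, deepest_landing + 1),
        toe_off=toe_off,
        full_foot_contact=full_foot,
    )
    meta = {
        "trial_id": trial_id,
        "kf_profile_deg": kf,
        "jump_distance_m": subject.jump_distance_m,
        "takeoff_velocity_up": v_z,
        "flight_T": flight_T,
        "crouch_deepest_frame": int(np.argmax(kf[:toe_off + 1])),
        "landing_deepest_frame": deepest_landing,
    }
    return _bundle(subject, "broad_jump", rate_hz, joints, events, meta)


# ---------------------------------------------------------------------------
# Observation rendering


def render_observation(
    truth: GroundTruthBundle, err: ErrorModel, seed: int | None = 0
) -> TrialTrajectory:
    """Render one system's observation of a ground-truth trial.

    Decimates to the system rate, adds i.i.d. Gaussian joint-center noise,
    applies the extension-weighted posterior hip bias, and (for jumps)
    injects the damped medio-lateral knee oscillation after toe-off and
    after landing.  Identical seeds give bit-identical output.
    """
    master = truth.trajectory.rate_hz
    ratio = master / err.rate_hz
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(f"system rate {err.rate_hz} must divide the master rate {master}")
    rng = np.random.default_rng(seed)
    joints = {j: truth.trajectory.joints[j][::factor].copy() for j in JOINTS}
    n = next(iter(joints.values())).shape[0]
    dt = 1.0 / err.rate_hz
    kf = truth.meta["kf_profile_deg"][::factor]

    # posterior hip bias, ramping 1 at full extension to 0 at the ramp angle
    if err.hip_posterior_bias_m > 0:
        w = np.clip(1.0 - kf / err.hip_bias_full_ramp_deg, 0.0, 1.0)
        for hip in ("hip_L", "hip_R"):
            joints[hip][:, 1] -= err.hip_posterior_bias_m * w  # -AP = posterior

    # impulsive wand wobble on the knee centers (jumps only)
    if err.wobble_amplitude_deg > 0 and truth.trajectory.movement == "broad_jump":
        subject_shank = _SHANK_F * _infer_height_m(truth)
        amp_m = np.tan(np.radians(err.wobble_amplitude_deg)) * subject_shank
        for event in (truth.events.toe_off, truth.events.full_foot_contact):
            if event is None:
                continue
            e = event // factor
            tt = (np.arange(n) - e) * dt
            burst = np.where(
                tt >= 0,
                amp_m * np.cos(2 * np.pi * err.wobble_freq_hz * tt) * np.exp(-tt / err.wobble_decay_s),
                0.0,
            )
            for knee in ("knee_L", "knee_R"):
                joints[knee][:, 0] += burst

    if err.iso_noise_sd_m > 0:
        for j in JOINTS:
            joints[j] += rng.normal(0.0, err.iso_noise_sd_m, size=joints[j].shape)

    return TrialTrajectory(
        subject_id=truth.trajectory.subject_id,
        trial_id=truth.trajectory.trial_id,
        movement=truth.trajectory.movement,
        system_id=err.system_id,
        rate_hz=err.rate_hz,
        joints=joints,
    )


def _infer_height_m(truth: GroundTruthBundle) -> float:
    # pelvis width back to stature, using the generator's fixed fraction
    w = np.linalg.norm(
        truth.trajectory.joints["hip_R"][0] - truth.trajectory.joints["hip_L"][0]
    )
    return float(w / _PELVIS_F)
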