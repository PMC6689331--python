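import numpy as np
import pytest

from mocapval.synthetic import (
    SubjectModel,
    generate_cohort,
    generate_jump_truth,
    generate_squat_truth,
)
from mocapval.trajectory import JOINTS, TrialTrajectory


@pytest.fixture(scope="session")
def subject():
    """A fixed mid-cohort child with no valgus tendency."""
    return SubjectModel(
        subject_id="S01",
        height_cm=109.2,
        squat_peak_flexion_deg=120.0,
        jump_distance_m=0.80,
        valgus_tendency_mm=0.0,
    )


@pytest.fixture(scope="session")
def valgus_subject():
    return SubjectModel(
        subject_id="S02",
        height_cm=105.0,
        squat_peak_flexion_deg=115.0,
        jump_distance_m=0.70,
        valgus_tendency_mm=20.0,
    )


@pytest.fixture(scope="session")
def squat_truth(subject):
    return generate_squat_truth(subject, duration_s=4.0, rate_hz=200.0, seed=11)


@pytest.fixture(scope="session")
def jump_truth(subject):
    return generate_jump_truth(subject, rate_hz=200.0, seed=12)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(14, seed=7)


def random_trajectory(rng: np.random.Generator, n_frames: int = 50,
                      rate_hz: float = 200.0) -> TrialTrajectory:
    """A geometrically plausible random trajectory for property checks."""
    joints = {}
    base = rng.normal(0.0, 0.5, size=(n_frames, 3))
    for j in JOINTS:
        joints[j] = base + rng.normal(0.0, 0.2, size=(n_frames, 3))
    # keep the hips apart so the frontal plane is defined
    joints["hip_L"][:, 0] -= 0.2
    joints["hip_R"][:, 0] += 0.2
    return TrialTrajectory(
        subject_id="R", trial_id="T", movement="squat", system_id="X",
        rate_hz=rate_hz, joints=joints,
    )
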