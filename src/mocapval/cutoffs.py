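"""Monte-Carlo derivation of LOA acceptance cut-offs and the grading rules.

When no external criterion says how wide limits of agreement may be before
a new system is useless, a pragmatic alternative is to simulate what LOA to
*expect* if both systems measured the same construct with plausible error:
system A (the reference) with an assumed error SD, system B with that SD
times 1.0, 1.5, and 2.0.  The averaged simulated LOA half-widths become the
good / acceptable / questionable / invalid boundaries for the observed
precision spans.  With independent Gaussian errors the half-width converges
to the closed form ``1.96 * sqrt(sigma_a^2 + sigma_b^2)``, which serves as
the analytic check on the simulation.

For the degree-family variables the assumed reference error SD is 5 deg,
for the separation-distance ratios 0.2, and for the frontal-plane knee
deviation 15 mm.

ICC point estimates are graded on the conventional poor / moderate / good /
excellent bands at 0.5, 0.75, and 0.9.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "ErrorScenario",
    "CutoffBands",
    "DEFAULT_SIGMA_A",
    "simulate_loa_cutoff",
    "closed_form_loa",
    "build_cutoff_bands",
    "classify_precision",
    "classify_icc",
]

LOA_MULTIPLIER = 1.96

#: assumed reference-system error SD per variable family
DEFAULT_SIGMA_A = {"degrees": 5.0, "ratio": 0.2, "mm": 15.0}

DEFAULT_MULTIPLIERS = (1.0, 1.5, 2.0)


@dataclasses.dataclass(frozen=True)
class ErrorScenario:
    """Two systems observing the same construct with independent errors."""

    sigma_a: float
    sigma_b: float
    n_trials: int = 1000
    n_obs: int = 1000
    seed: int | None = None
    truth_sd: float = 1.0  # spread of the true values; cancels in the differences

    def __post_init__(self) -> None:
        if self.sigma_a < 0 or self.sigma_b < 0 or self.truth_sd < 0:
            raise ValueError("error SDs must be >= 0")
        if self.n_trials < 1 or self.n_obs < 1:
            raise ValueError("n_trials and n_obs must be >= 1")


@dataclasses.dataclass(frozen=True)
class CutoffBands:
    """Three half-width thresholds splitting spans into four grades."""

    family: str  # degrees | ratio | mm
    good_lt: float
    acceptable_lt: float
    questionable_lt: float

    LABELS = ("good", "acceptable", "questionable", "invalid")

    def __post_init__(self) -> None:
        if not self.good_lt < self.acceptable_lt < self.questionable_lt:
            raise ValueError("thresholds must be strictly increasing")


def simulate_loa_cutoff(scenario: ErrorScenario) -> float:
    """Mean LOA half-width over simulated trials of paired noisy observations.

    Each trial draws ``n_obs`` true values, adds independent zero-mean
    Gaussian errors with the two scenario SDs, and computes the half-width
    ``1.96 * SD(differences)``; the mean over trials is returned.  The true
    values cancel in the differences, so the result is invariant to their
    distribution.  Observations within a trial are i.i.d., so the simple
    SD (no repeated-measures correction) applies.
    """
    rng = np.random.default_rng(scenario.seed)
    half_widths = np.empty(scenario.n_trials)
    for t in range(scenario.n_trials):
        truth = rng.normal(0.0, scenario.truth_sd, size=scenario.n_obs)
        a = truth + rng.normal(0.0, scenario.sigma_a, size=scenario.n_obs)
        b = truth + rng.normal(0.0, scenario.sigma_b, size=scenario.n_obs)
        half_widths[t] = LOA_MULTIPLIER * np.std(b - a, ddof=1)
    return float(np.mean(half_widths))


def closed_form_loa(sigma_a: float, sigma_b: float) -> float:
    """Analytic LOA half-width for independent Gaussian errors."""
    return LOA_MULTIPLIER * math.hypot(sigma_a, sigma_b)


def build_cutoff_bands(
    sigma_a: float,
    family: str = "degrees",
    multipliers: tuple[float, float, float] = DEFAULT_MULTIPLIERS,
    n_trials: int = 1000,
    n_obs: int = 1000,
    seed: int | None = None,
) -> CutoffBands:
    """Simulate the three cut-points for one variable family.

    System B's error SD is ``sigma_a`` times each multiplier; the three
    averaged half-widths become the band thresholds.
    """
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    if len(multipliers) != 3:
        raise ValueError("exactly three multipliers are required")
    seeds = (
        (None, None, None)
        if seed is None
        else np.random.SeedSequence(seed).generate_state(3) % (2**31)
    )
    thresholds = [
        simulate_loa_cutoff(
            ErrorScenario(
                sigma_a, sigma_a * m, n_trials=n_trials, n_obs=n_obs,
                seed=None if s is None else int(s),
            )
        )
        for m, s in zip(multipliers, seeds)
    ]
    return CutoffBands(family, *thresholds)


def classify_precision(lloa: float, uloa: float, bands: CutoffBands) -> str:
    """Grade an LOA interval by its half-width, ignoring the mean difference.

    Boundary convention: a half-width exactly at a threshold falls in the
    worse grade (thresholds are strict upper bounds).
    """
    if lloa > uloa:
        raise ValueError("lloa must not exceed uloa")
    half = (uloa - lloa) / 2.0
    if half < bands.good_lt:
        return "good"
    if half < bands.acceptable_lt:
        return "acceptable"
    if half < bands.questionable_lt:
        return "questionable"
    return "invalid"


def classify_icc(value: float) -> str:
    """Grade an ICC point estimate: poor / moderate / good / excellent.

    Bands are left-closed: [0.5, 0.75) moderate, [0.75, 0.9) good,
    >= 0.9 excellent.  NaN returns "undefined".  Sample estimates of the
    agreement form can stray slightly outside [-1, 1] (the denominator
    shrinks when the rater mean square falls below the error mean square);
    such values are graded monotonically rather than rejected.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "undefined"
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"
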