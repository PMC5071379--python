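"""Synthetic psychophysical experiments: designs, endpoints, trajectories.

Emulates the two center-localization experiments that the models describe:

* **Experiment 1** — bilateral repulsive fields, 7 stiffness pairs
  {(16,4),(16,8),(8,4),(4,8),(8,16),(4,16),(8,8)} N/m crossed with visual
  feedback present/absent, 6 trials per condition (84 per participant);
* **Experiment 2** — unilateral attractive fields ("find the edge of a
  virtual object"), K in {4,8,16} N/m on the left or right, 6 trials per
  condition (36 per participant).

Field centers are drawn uniformly within three 2-cm regions of the
workspace and start positions 1–3 cm from the center (mirrored start sides
in Experiment 1; outside the object in Experiment 2).  Endpoints are drawn
from a chosen generative model (bisection or stiffness); optional 250-Hz
exploration trajectories reproduce the oscillate-then-converge movement
pattern so the full preprocessing chain can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .models import (
    BisectionParams,
    Feedback,
    ForceField,
    Orientation,
    ProbeMode,
    PsychophysicalLaw,
    StiffnessProbe,
    bisection_bias,
    bisection_sd,
    stiffness_bilateral_bias,
    stiffness_unilateral_bias,
)

__all__ = [
    "EXP1_STIFFNESS_PAIRS",
    "EXP2_STIFFNESSES",
    "SAMPLE_RATE",
    "Condition",
    "TrialDesign",
    "TrialRecord",
    "TrajectoryProfile",
    "StiffnessGenerator",
    "exp1_conditions",
    "exp2_conditions",
    "conditions_for",
    "generate_design",
    "model_prediction",
    "simulate_endpoint",
    "simulate_trajectory",
    "simulate_participant",
    "simulate_cohort_endpoints",
]

#: (K_left, K_right) pairs of Experiment 1, N/m; six asymmetric + one symmetric.
EXP1_STIFFNESS_PAIRS: tuple[tuple[float, float], ...] = (
    (16.0, 4.0), (16.0, 8.0), (8.0, 4.0),
    (4.0, 8.0), (8.0, 16.0), (4.0, 16.0), (8.0, 8.0),
)

#: Unilateral spring stiffnesses of Experiment 2, N/m.
EXP2_STIFFNESSES: tuple[float, ...] = (4.0, 8.0, 16.0)

#: Recording rate of the haptic device, Hz.
SAMPLE_RATE: float = 250.0

# field-center randomization regions relative to the workspace middle, m
_REGIONS: tuple[tuple[float, float], ...] = ((-0.03, -0.01), (-0.01, 0.01),
                                             (0.01, 0.03))
_START_DIST: tuple[float, float] = (0.01, 0.03)  # |start - center| range, m


@dataclass(frozen=True)
class Condition:
    """One cell of an experiment's design."""

    experiment: Literal["exp1", "exp2"]
    K_left: float
    K_right: float
    feedback: Feedback = Feedback.NA
    side: Literal["left", "right", "bilateral"] = "bilateral"

    def __post_init__(self) -> None:
        if self.experiment == "exp1":
            if self.side != "bilateral" or self.feedback is Feedback.NA:
                raise ValueError("exp1 conditions are bilateral with feedback")
        elif self.experiment == "exp2":
            if self.side == "bilateral" or self.feedback is not Feedback.NA:
                raise ValueError("exp2 conditions are unilateral, no feedback")
        else:
            raise ValueError(f"unknown experiment {self.experiment!r}")

    @property
    def label(self) -> str:
        if self.experiment == "exp1":
            return (f"exp1 K={self.K_left:g}/{self.K_right:g} "
                    f"fb={self.feedback.value}")
        K = self.K_right if self.side == "right" else self.K_left
        return f"exp2 K={K:g} side={self.side}"

    def force_field(self, center: float = 0.0) -> ForceField:
        orient = (Orientation.REPULSIVE if self.experiment == "exp1"
                  else Orientation.ATTRACTIVE)
        return ForceField(self.K_left, self.K_right, center, orient)


@dataclass(frozen=True)
class TrialDesign:
    """One trial: condition, randomized center and start (workspace frame, m)."""

    condition: Condition
    center: float
    start: float
    region_index: int  # 1..3
    tag: str  # start-side or repetition tag


@dataclass
class TrialRecord:
    """Recorded samples of one simulated trial (250 Hz)."""

    design: TrialDesign
    t: np.ndarray          # s
    x: np.ndarray          # hand position, m, workspace frame
    F_measured: np.ndarray  # rendered force, N
    quality_flag: np.ndarray  # boolean; True marks high-frequency-noise epochs
    end_pressed_at: float   # s


def exp1_conditions() -> list[Condition]:
    return [Condition("exp1", kl, kr, feedback=fb)
            for kl, kr in EXP1_STIFFNESS_PAIRS
            for fb in (Feedback.PRESENT, Feedback.ABSENT)]


def exp2_conditions() -> list[Condition]:
    out = []
    for K in EXP2_STIFFNESSES:
        out.append(Condition("exp2", K, 0.0, side="left"))
        out.append(Condition("exp2", 0.0, K, side="right"))
    return out


def conditions_for(experiment: str) -> list[Condition]:
    if experiment == "exp1":
        return exp1_conditions()
    if experiment == "exp2":
        return exp2_conditions()
    raise ValueError(f"unknown experiment {experiment!r}")


def generate_design(experiment: str,
                    seed: int | np.random.SeedSequence) -> list[TrialDesign]:
    """Randomized per-participant trial list.

    Experiment 1: for each condition, one random center per region and one
    random start distance per center, used on both sides of the center
    (mirror balance) — 6 trials per condition, 84 total.  Experiment 2: two
    repetitions per region with fresh centers and distances, starts placed
    outside the object (on the force-free side of the edge) — 36 total.
    """
    rng = np.random.default_rng(seed)
    designs: list[TrialDesign] = []
    for cond in conditions_for(experiment):
        for i_region, (lo, hi) in enumerate(_REGIONS, start=1):
            if experiment == "exp1":
                center = rng.uniform(lo, hi)
                dist = rng.uniform(*_START_DIST)
                for side, s in (("left", center - dist), ("right", center + dist)):
                    designs.append(TrialDesign(cond, center, s, i_region,
                                               f"start_{side}"))
            else:
                for rep in (1, 2):
                    center = rng.uniform(lo, hi)
                    dist = rng.uniform(*_START_DIST)
                    # start on the side without a spring, outside the object
                    s = center - dist if cond.side == "right" else center + dist
                    designs.append(TrialDesign(cond, center, s, i_region,
                                               f"rep_{rep}"))
    return designs


# ---------------------------------------------------------------------------
# Generative models for endpoints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StiffnessGenerator:
    """Endpoint generator for the stiffness-extrapolation account.

    Endpoints sit at the extrapolated edge estimate for an equal-force probe
    at ``probe_force`` plus positional noise of SD ``sigma_P``.
    """

    law: PsychophysicalLaw
    probe_force: float
    sigma_P: float = 0.0


def model_prediction(design: TrialDesign,
                     generator: Literal["bisection", "stiffness"],
                     params: BisectionParams | StiffnessGenerator
                     ) -> tuple[float, float]:
    """(mean offset from center, SD) of the endpoint distribution, m."""
    cond = design.condition
    field = cond.force_field(center=0.0)
    if generator == "bisection":
        assert isinstance(params, BisectionParams)
        return (bisection_bias(field, params),
                bisection_sd(field, params, cond.feedback))
    if generator == "stiffness":
        assert isinstance(params, StiffnessGenerator)
        if field.bilateral:
            mu = stiffness_bilateral_bias(
                params.law, field,
                StiffnessProbe(ProbeMode.EQUAL_FORCE,
                               probe_force=params.probe_force))
        else:
            mu = stiffness_unilateral_bias(params.law, field,
                                           params.probe_force)
        return mu, params.sigma_P
    raise ValueError(f"unknown generator {generator!r}")


def simulate_endpoint(design: TrialDesign,
                      generator: Literal["bisection", "stiffness"],
                      params: BisectionParams | StiffnessGenerator,
                      rng: int | np.random.Generator) -> float:
    """One endpoint draw: center + model bias + Normal(0, model SD), m."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu, sd = model_prediction(design, generator, params)
    return design.center + mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)


# ---------------------------------------------------------------------------
# Exploration trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryProfile:
    """Shape parameters of the simulated exploration movement.

    Defaults follow the observed movement statistics: roughly 11-s trials
    with about 11 direction changes for bilateral fields, 8.5 s and 8
    changes for the unilateral ones.  The oscillation amplitude decays
    exponentially ("zooming in"); the final ``settle`` seconds rest exactly
    at the endpoint.
    """

    duration: float = 10.9
    n_direction_changes: float = 11.1
    decay_rate: float = 0.4   # 1/s, amplitude decay
    settle: float = 0.15      # s held at the endpoint before the button press

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.settle < 0 or self.settle >= self.duration:
            raise ValueError("settle must lie in [0, duration)")

    @classmethod
    def for_experiment(cls, experiment: str) -> "TrajectoryProfile":
        if experiment == "exp1":
            return cls()
        return cls(duration=8.5, n_direction_changes=8.2)


def simulate_trajectory(design: TrialDesign, endpoint: float,
                        profile: TrajectoryProfile | None = None,
                        flagged_epoch: tuple[float, float] | None = None
                        ) -> TrialRecord:
    """Damped oscillatory hand path from the start to the endpoint.

    The hand first oscillates across the field center (so a bilateral
    trial's force trace crosses zero several times) with exponentially
    decaying amplitude, while the oscillation midline slides from the true
    center toward the endpoint — the "zoom in" pattern.  The last ``settle``
    seconds are held exactly at the endpoint so the endpoint-extraction
    contract (mean of the final 100 ms) is exact.  Forces follow the trial's
    field law at each sampled position.  ``flagged_epoch=(t0, dur)`` marks a
    run of samples with the quality flag raised, for exercising the
    rejection filter.
    """
    if profile is None:
        profile = TrajectoryProfile.for_experiment(design.condition.experiment)
    dt = 1.0 / SAMPLE_RATE
    n = int(round(profile.duration * SAMPLE_RATE)) + 1
    t = np.arange(n) * dt
    center = design.center
    start_off = design.start - center
    offset = endpoint - center
    # a cosine reverses direction twice per period
    freq = profile.n_direction_changes / (2.0 * profile.duration)
    # amplitude large enough that the hand sweeps across the center for at
    # least ~1.25 oscillation periods before the decaying envelope drops
    # below the midline offset (guarantees >= 2 force zero-crossings)
    period = 1.0 / freq
    grow = math.exp(1.25 * period * profile.decay_rate) - 1.0
    amp = max(abs(start_off), grow * abs(offset), 0.01)
    phase = math.acos(min(1.0, max(-1.0, start_off / amp)))
    decay = np.exp(-profile.decay_rate * t)
    midline = center + offset * (1.0 - decay)
    x = midline + amp * decay * np.cos(2.0 * np.pi * freq * t + phase)
    x[t >= profile.duration - profile.settle] = endpoint
    field = design.condition.force_field(center=design.center)
    F = np.array([field.force_at(xi) for xi in x])
    flag = np.zeros(n, dtype=bool)
    if flagged_epoch is not None:
        t0, dur = flagged_epoch
        flag[(t >= t0) & (t < t0 + dur)] = True
    return TrialRecord(design, t, x, F, flag, end_pressed_at=float(t[-1]))


# ---------------------------------------------------------------------------
# Participant- and cohort-level convenience layers
# ---------------------------------------------------------------------------

def simulate_participant(experiment: str,
                         generator: Literal["bisection", "stiffness"],
                         params: BisectionParams | StiffnessGenerator,
                         seed: int | np.random.SeedSequence,
                         trajectories: bool = True,
                         profile: TrajectoryProfile | None = None
                         ) -> list[TrialRecord] | list[tuple[TrialDesign, float]]:
    """Full synthetic dataset for one participant.

    Design randomization and endpoint noise run on independent substreams of
    the participant seed, so designs are identical across generators for the
    same seed.  With ``trajectories=False`` only (design, endpoint) pairs
    are returned, which is all the summary statistics need.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    design_ss, noise_ss = ss.spawn(2)
    designs = generate_design(experiment, design_ss)
    rng = np.random.default_rng(noise_ss)
    endpoints = [simulate_endpoint(d, generator, params, rng) for d in designs]
    if not trajectories:
        return list(zip(designs, endpoints))
    return [simulate_trajectory(d, e, profile)
            for d, e in zip(designs, endpoints)]


def simulate_cohort_endpoints(experiment: str,
                              generator: Literal["bisection", "stiffness"],
                              params: BisectionParams | StiffnessGenerator,
                              n_participants: int,
                              seed: int | np.random.SeedSequence
                              ) -> list[list[tuple[TrialDesign, float]]]:
    """(design, endpoint) datasets for a cohort of simulated participants."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    return [simulate_participant(experiment, generator, params, child,
                                 trajectories=False)
            for child in ss.spawn(n_participants)]
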