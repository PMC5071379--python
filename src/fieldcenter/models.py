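"""Closed-form predictions for haptic force-field center estimation.

Two competing accounts of how people locate the center of a weak elastic
force field are implemented:

* the **bisection model** — the perceived center is the (weighted) midpoint
  of the position(s) where the force magnitude reaches the detection
  threshold ``F_th``; it predicts a bias of ``F_th / K`` toward the weaker
  (or only) spring, and a response variability that combines force-threshold
  noise (scaled by ``1/K``) with positional noise;

* the **stiffness model** — the observer estimates the field's stiffness
  from supra-threshold probing and extrapolates the perceived force down to
  zero along a Stevens power-law transducer; with exponent ``beta < 1`` the
  extrapolation overshoots, so predicted biases are *smaller* than the
  bisection ones and shrink with probe depth.

All model math lives in a field-centered frame: the origin sits at the true
field center and positive positions are rightward.  Units are SI throughout
(N, m, N/m); unit conversion belongs at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Feedback",
    "Orientation",
    "ProbeMode",
    "PsychophysicalLaw",
    "ForceField",
    "BisectionParams",
    "StiffnessProbe",
    "Prediction",
    "perceived_force",
    "bisection_bias",
    "bisection_sd",
    "bisection_prediction",
    "stiffness_center_estimate",
    "stiffness_bilateral_bias",
    "stiffness_unilateral_bias",
    "prediction_band",
    "LITERATURE_FTH_RANGE",
    "LINEAR_FIELD_EXTENT",
]

#: Force-detection thresholds reported in the psychophysical literature, N.
LITERATURE_FTH_RANGE: tuple[float, float] = (0.05, 0.10)

#: Half-width of the linear part of the rendered force field, m.
LINEAR_FIELD_EXTENT: float = 0.06


class Feedback(str, Enum):
    """Visual-feedback condition of a trial (drives the ``k`` switch)."""

    PRESENT = "present"
    ABSENT = "absent"
    NA = "n/a"


class Orientation(str, Enum):
    """Direction of the rendered spring forces relative to the center."""

    REPULSIVE = "repulsive"  # bilateral fields push outward
    ATTRACTIVE = "attractive"  # unilateral fields pull toward the edge


class ProbeMode(str, Enum):
    POSITIONS = "positions"
    EQUAL_FORCE = "equal_force"


@dataclass(frozen=True)
class PsychophysicalLaw:
    """Stevens power-law transducer from physical to perceived force.

    Perceived force is ``alpha * (F - F_th)**beta`` above the detection
    threshold ``F_th`` and zero below it.  ``alpha`` cancels out of every
    center prediction (it rescales both the force sample and the estimated
    stiffness); it is kept for completeness.
    """

    alpha: float = 1.0
    beta: float = 0.8
    F_th: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.F_th < 0:
            raise ValueError(f"F_th must be >= 0, got {self.F_th}")


@dataclass(frozen=True)
class ForceField:
    """One trial's elastic force field.

    ``K_left`` / ``K_right`` are the spring stiffnesses active left/right of
    the center (0 means no spring on that side).  ``center`` is the true
    field center in workspace coordinates; model predictions are expressed
    relative to it.
    """

    K_left: float
    K_right: float
    center: float = 0.0
    orientation: Orientation = Orientation.REPULSIVE

    def __post_init__(self) -> None:
        if self.K_left < 0 or self.K_right < 0:
            raise ValueError("stiffnesses must be >= 0")
        if self.K_left == 0 and self.K_right == 0:
            raise ValueError("at least one spring stiffness must be > 0")

    @property
    def bilateral(self) -> bool:
        return self.K_left > 0 and self.K_right > 0

    @property
    def unilateral_side(self) -> str:
        if self.bilateral:
            raise ValueError("field is bilateral")
        return "right" if self.K_right > 0 else "left"

    def mirrored(self) -> "ForceField":
        """Swap the two springs (reflection about the center)."""
        return ForceField(self.K_right, self.K_left, self.center, self.orientation)

    def force_at(self, x: float) -> float:
        """Rendered force at workspace position ``x`` (signed, N).

        Repulsive (bilateral) fields point away from the center, so the
        force changes sign there; attractive (unilateral) fields point back
        toward the center on the spring side and vanish elsewhere.
        """
        d = x - self.center
        if self.orientation is Orientation.REPULSIVE:
            K = self.K_right if d >= 0 else self.K_left
            return K * d
        # attractive: force opposes penetration into the spring region
        if d >= 0:
            return -self.K_right * d
        return -self.K_left * d


@dataclass(frozen=True)
class BisectionParams:
    """Parameters of the bisection model's bias/variability predictions.

    ``sigma_P_fp`` and ``sigma_P_fa`` are the positional noise SDs with
    visual feedback present and absent; unilateral (no-feedback) predictions
    use ``sigma_P_fa``.  ``w`` weights the right-side threshold position and
    is fixed at 1/2 for a device at the body midline.
    """

    F_th: float
    sigma_Fth: float = 0.0
    sigma_P_fp: float = 0.0
    sigma_P_fa: float = 0.0
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.F_th < 0:
            raise ValueError("F_th must be >= 0")
        if min(self.sigma_Fth, self.sigma_P_fp, self.sigma_P_fa) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")

    @classmethod
    def unilateral(cls, F_th: float, sigma_F: float = 0.0,
                   sigma_P: float = 0.0) -> "BisectionParams":
        """Construct the three-parameter unilateral variant (single sigma_P)."""
        return cls(F_th=F_th, sigma_Fth=sigma_F,
                   sigma_P_fp=sigma_P, sigma_P_fa=sigma_P)

    def sigma_P(self, feedback: Feedback) -> float:
        if feedback is Feedback.PRESENT:
            return self.sigma_P_fp
        return self.sigma_P_fa


@dataclass(frozen=True)
class StiffnessProbe:
    """Where the stiffness model's per-side estimates are made.

    In ``equal_force`` mode both sides are probed at the same force
    magnitude ``probe_force`` (the only probing assumption the geometry of
    the two-sided extrapolation suggests); in ``positions`` mode explicit
    hand positions are given in the field-centered frame.
    """

    probe_mode: ProbeMode = ProbeMode.EQUAL_FORCE
    probe_force: float | None = None
    x_left: float | None = None
    x_right: float | None = None


@dataclass(frozen=True)
class Prediction:
    """Predicted signed bias and within-participant SD, m."""

    mu_x: float
    sigma_x: float

    def __post_init__(self) -> None:
        if self.sigma_x < 0:
            raise ValueError("sigma_x must be >= 0")


# ---------------------------------------------------------------------------
# Psychophysical transducer
# ---------------------------------------------------------------------------

def perceived_force(law: PsychophysicalLaw, F: float) -> float:
    """Perceived magnitude of a physical force ``F`` >= 0.

    Zero at and below the detection threshold, ``alpha*(F - F_th)**beta``
    above it.
    """
    if F < 0:
        raise ValueError(f"physical force must be >= 0, got {F}")
    if F <= law.F_th:
        return 0.0
    return law.alpha * (F - law.F_th) ** law.beta


# ---------------------------------------------------------------------------
# Bisection model
# ---------------------------------------------------------------------------

def bisection_bias(field: ForceField, params: BisectionParams) -> float:
    """Predicted signed endpoint bias under the bisection model, m.

    Bilateral: ``(1-w)(-F_th/K_left) + w(F_th/K_right)`` — the weighted
    midpoint of the two threshold positions.  Unilateral: ``F_th/K`` toward
    the spring (positive for a right-side spring).
    """
    if field.bilateral:
        return ((1.0 - params.w) * (-params.F_th / field.K_left)
                + params.w * (params.F_th / field.K_right))
    if field.K_right > 0:
        return params.F_th / field.K_right
    return -params.F_th / field.K_left


def bisection_sd(field: ForceField, params: BisectionParams,
                 feedback: Feedback = Feedback.NA) -> float:
    """Predicted within-participant endpoint SD under the bisection model, m.

    Bilateral fields combine force-threshold noise at both threshold
    positions with positional noise (the ``k`` switch selects the
    feedback-present or feedback-absent positional SD).  Unilateral fields
    use the single-sided variance sum.
    """
    if field.bilateral:
        if feedback is Feedback.NA:
            raise ValueError("bilateral prediction needs a feedback condition")
        sP = params.sigma_P(feedback)
        var = 0.25 * (params.sigma_Fth ** 2 / field.K_left ** 2
                      + params.sigma_Fth ** 2 / field.K_right ** 2
                      + 2.0 * sP ** 2)
        return math.sqrt(var)
    K = field.K_right if field.K_right > 0 else field.K_left
    sP = params.sigma_P_fa
    return math.sqrt(params.sigma_Fth ** 2 / K ** 2 + sP ** 2)


def bisection_prediction(field: ForceField, params: BisectionParams,
                         feedback: Feedback = Feedback.NA) -> Prediction:
    return Prediction(bisection_bias(field, params),
                      bisection_sd(field, params, feedback))


# ---------------------------------------------------------------------------
# Stiffness model
# ---------------------------------------------------------------------------

def _require_supra_threshold(x: float, x0: float) -> None:
    # the supra-threshold region lies beyond x0, on x0's side of the center
    if x0 > 0 and x < x0:
        raise ValueError(f"probe x={x} is sub-threshold (x0={x0})")
    if x0 < 0 and x > x0:
        raise ValueError(f"probe x={x} is sub-threshold (x0={x0})")


def stiffness_center_estimate(law: PsychophysicalLaw, x: float,
                              x0: float) -> float:
    """Field-edge position extrapolated from a probe at ``x``, m.

    The observer senses the perceived force at ``x``, divides by the locally
    perceived stiffness (the slope of the power-law transducer), and steps
    that distance toward zero force: the estimate is ``x - (x - x0)/beta``
    where ``x0`` is the position where perceived force vanishes.  With
    ``beta = 1`` the estimate is exactly ``x0``; with ``beta < 1`` it
    overshoots past ``x0``, increasingly so for deeper probes.
    """
    _require_supra_threshold(x, x0)
    return x - (x - x0) / law.beta


def _probe_positions(law: PsychophysicalLaw, field: ForceField,
                     probe: StiffnessProbe) -> tuple[float, float]:
    if probe.probe_mode is ProbeMode.EQUAL_FORCE:
        if probe.probe_force is None:
            raise ValueError("equal_force mode requires probe_force")
        if probe.probe_force <= law.F_th:
            raise ValueError(
                f"probe_force={probe.probe_force} must exceed F_th={law.F_th}")
        return (-probe.probe_force / field.K_left,
                probe.probe_force / field.K_right)
    if probe.x_left is None or probe.x_right is None:
        raise ValueError("positions mode requires x_left and x_right")
    return probe.x_left, probe.x_right


def stiffness_bilateral_bias(law: PsychophysicalLaw, field: ForceField,
                             probe: StiffnessProbe) -> float:
    """Predicted bias of the stiffness model for a bilateral field, m.

    The mean of the two per-side extrapolated edge positions, with the
    perceived-force zeros at the threshold positions ``-F_th/K_left`` and
    ``+F_th/K_right``.
    """
    if not field.bilateral:
        raise ValueError("bilateral field required; use stiffness_unilateral_bias")
    x_left, x_right = _probe_positions(law, field, probe)
    x0_left = -law.F_th / field.K_left
    x0_right = law.F_th / field.K_right
    est_left = stiffness_center_estimate(law, x_left, x0_left)
    est_right = stiffness_center_estimate(law, x_right, x0_right)
    return 0.5 * (est_left + est_right)


def stiffness_unilateral_bias(law: PsychophysicalLaw, field: ForceField,
                              probe_force: float) -> float:
    """Single-sided stiffness-model bias: the extrapolated edge position, m."""
    if field.bilateral:
        raise ValueError("unilateral field required")
    if probe_force <= law.F_th:
        raise ValueError(f"probe_force={probe_force} must exceed F_th={law.F_th}")
    if field.K_right > 0:
        x0 = law.F_th / field.K_right
        x = probe_force / field.K_right
    else:
        x0 = -law.F_th / field.K_left
        x = -probe_force / field.K_left
    return stiffness_center_estimate(law, x, x0)


# ---------------------------------------------------------------------------
# Prediction bands
# ---------------------------------------------------------------------------

def default_probe_sweep(field: ForceField, F_th: float,
                        n: int = 25) -> list[float]:
    """Probe forces spanning (F_th, F_max], F_max set by the linear extent.

    The weakest active spring limits the largest force reachable within the
    linear +/-6 cm region of the workspace.
    """
    Ks = [K for K in (field.K_left, field.K_right) if K > 0]
    F_max = min(Ks) * LINEAR_FIELD_EXTENT
    if F_max <= F_th:
        raise ValueError("linear field extent lies entirely below threshold")
    step = (F_max - F_th) / n
    return [F_th + step * (i + 1) for i in range(n)]


def prediction_band(field: ForceField,
                    F_th_range: Sequence[float] = LITERATURE_FTH_RANGE,
                    model: str = "bisection",
                    probe_sweep: Iterable[float] | None = None,
                    beta: float = 0.8) -> tuple[float, float]:
    """Interval of predicted biases over a range of detection thresholds, m.

    For the bisection model the band runs between the biases at the two ends
    of ``F_th_range`` (the bias is monotone in ``F_th``).  For the stiffness
    model it is the envelope of the extrapolation bias over the probe-force
    sweep (by default spanning threshold to the linear field edge), which
    reaches from just under the bisection band edge down toward zero.
    Returned as ``(low, high)`` sorted numerically.
    """
    F_ths = list(F_th_range)
    if len(F_ths) == 0:
        raise ValueError("empty F_th range")
    lo, hi = min(F_ths), max(F_ths)
    if model == "bisection":
        biases = [bisection_bias(field, BisectionParams(F_th=f)) for f in (lo, hi)]
        return min(biases), max(biases)
    if model != "stiffness":
        raise ValueError(f"unknown model {model!r}")
    biases = []
    for F_th in (lo, hi):
        law = PsychophysicalLaw(beta=beta, F_th=F_th)
        sweep = list(probe_sweep) if probe_sweep is not None \
            else default_probe_sweep(field, F_th)
        for F in sweep:
            if F <= F_th:
                continue
            if field.bilateral:
                biases.append(stiffness_bilateral_bias(
                    law, field, StiffnessProbe(probe_force=F)))
            else:
                biases.append(stiffness_unilateral_bias(law, field, F))
    if not biases:
        raise ValueError("probe sweep contains no supra-threshold force")
    return min(biases), max(biases)
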