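"""The inverted-double-pendulum step-length model with pelvic rotation.

Each step is decomposed per phase (braking E1, propulsion E2) into

* a pendular term: the leg acts as an inverted pendulum, so the forward
  velocity obeys ``V = C * L`` with ``C`` the phase cadence (reciprocal of
  the phase duration).  Normalizing by the Froude number
  ``Fr = V^2 / (g * Lp)`` makes the term comparable across body sizes; the
  dimensionally consistent solution is ``L_pendular = sqrt(Fr * g * Lp) / C``,
  algebraically equal to ``V / C`` — the kinematic phase displacement.
* a pelvic term: the transverse pelvic rotation projects onto the direction
  of travel through the pelvic lever arm, ``L_pelvic = rp * tan(yaw)``, with
  the full tangent kept (rather than a small-angle form) so the projection
  stays valid at the larger compensatory angles of impaired gait.  Observed
  pelvic rotation stays within about +/-20 degrees, far from the tangent
  singularities.

The total step length is the sum over both phases of the pendular term and
the signed pelvic term.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signals import SubjectAnthropometrics

__all__ = [
    "StepEstimate",
    "PhaseKinematics",
    "froude",
    "pendular_length",
    "pelvic_length",
    "phase_cadence",
    "step_length",
]

# Sign applied to the pelvic projection when assembling the total, matching
# the model's printed form (pendular minus rp*tan(yaw) per phase).  Flip via
# the ``pelvic_sign`` configuration if a sensor convention requires it.
DEFAULT_PELVIC_SIGN = -1.0
YAW_WARN_DEG = 45.0


@dataclass
class PhaseKinematics:
    """Kinematic summary of one phase, input to the step-length model."""

    v_mean: float  # m/s, integrated average velocity of the phase
    duration: float  # s
    yaw_start: float  # degrees, filtered pelvic yaw at phase start
    yaw_end: float  # degrees, filtered pelvic yaw at phase end

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")

    @property
    def yaw_delta(self) -> float:
        return self.yaw_end - self.yaw_start


@dataclass
class StepEstimate:
    """Per-step length estimate with its pendular/pelvic decomposition."""

    step_index: int
    side: str
    t_ic: float
    t_ms: float
    t_ic_next: float
    L_pendular_E1: float
    L_pendular_E2: float
    L_pelvic_E1: float  # signed contribution (model sign already applied)
    L_pelvic_E2: float
    L_total: float
    Fr_E1: float
    Fr_E2: float
    C_E1: float
    C_E2: float
    yaw_E1: float
    yaw_E2: float
    v_E1: float
    v_E2: float
    analyzed: bool = True


def froude(v: float, lp: float, g: float) -> float:
    """Froude number ``Fr = v^2 / (g * lp)`` (dimensionless)."""
    if lp <= 0 or g <= 0:
        raise ValueError("leg length and gravity must be positive")
    return float(v) ** 2 / (g * lp)


def pendular_length(Fr: float, lp: float, C: float, g: float) -> float:
    """Pendular phase length ``sqrt(Fr * g * lp) / C`` (equals |v| / C)."""
    if C <= 0:
        raise ValueError("phase cadence must be positive")
    if Fr < 0:
        raise ValueError("Froude number cannot be negative")
    return float(np.sqrt(Fr * g * lp) / C)


def pelvic_length(rp: float, yaw_deg: float) -> float:
    """Signed pelvic projection ``rp * tan(yaw)``; yaw in degrees.

    Hard error at or beyond the tangent singularity (90 degrees); a warning
    above 45 degrees, well outside the physiologic range.
    """
    if abs(yaw_deg) >= 90.0:
        raise ValueError(f"pelvic yaw of {yaw_deg:.1f} deg reaches the tangent singularity")
    if abs(yaw_deg) > YAW_WARN_DEG:
        warnings.warn(f"pelvic yaw of {yaw_deg:.1f} deg is outside the physiologic range", stacklevel=2)
    return float(rp * np.tan(np.radians(yaw_deg)))


def phase_cadence(duration: float) -> float:
    """Phase cadence ``C = 1 / duration`` (1/s).

    With this choice the pendular term ``v / C`` equals the kinematic
    displacement ``v * duration`` of the phase.
    """
    if duration <= 0:
        raise ValueError("phase duration must be positive")
    return 1.0 / duration


def step_length(
    e1: PhaseKinematics,
    e2: PhaseKinematics,
    anthro: SubjectAnthropometrics,
    side: str,
    step_index: int = 0,
    t_ic: float = 0.0,
    pelvic_sign: float = DEFAULT_PELVIC_SIGN,
    analyzed: bool = True,
) -> StepEstimate:
    """Assemble the per-step length estimate from phase kinematics.

    The stance side's leg length enters the Froude normalization; the yaw
    argument of the pelvic term is the net change of the filtered yaw over
    each phase.  The stored pelvic components carry the model sign, so the
    decomposition always sums exactly to ``L_total``.
    """
    lp = anthro.leg_length(side)
    g = anthro.g
    C1, C2 = phase_cadence(e1.duration), phase_cadence(e2.duration)
    # speeds enter through |v|; a transient backward excursion cannot make
    # the pendular term negative
    Fr1, Fr2 = froude(e1.v_mean, lp, g), froude(e2.v_mean, lp, g)
    Lp1, Lp2 = pendular_length(Fr1, lp, C1, g), pendular_length(Fr2, lp, C2, g)
    Pe1 = pelvic_sign * pelvic_length(anthro.rp, e1.yaw_delta)
    Pe2 = pelvic_sign * pelvic_length(anthro.rp, e2.yaw_delta)
    total = Lp1 + Pe1 + Lp2 + Pe2
    return StepEstimate(
        step_index=step_index,
        side=side,
        t_ic=t_ic,
        t_ms=t_ic + e1.duration,
        t_ic_next=t_ic + e1.duration + e2.duration,
        L_pendular_E1=Lp1,
        L_pendular_E2=Lp2,
        L_pelvic_E1=Pe1,
        L_pelvic_E2=Pe2,
        L_total=total,
        Fr_E1=Fr1,
        Fr_E2=Fr2,
        C_E1=C1,
        C_E2=C2,
        yaw_E1=e1.yaw_delta,
        yaw_E2=e2.yaw_delta,
        v_E1=e1.v_mean,
        v_E2=e2.v_mean,
        analyzed=analyzed,
    )
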