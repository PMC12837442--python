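"""Phase-segmented velocity reconstruction (OFDRI).

Anteroposterior acceleration is low-pass filtered at 3.5 Hz and integrated
with the trapezoidal rule, phase by phase.  Initial conditions chain across
phases: the first braking phase of a trial starts at zero velocity — the
method assumes trials begin at a standstill, with the first contact taken
at gait initiation — each propulsion phase starts at the braking phase's
final velocity, and each subsequent braking phase at the final velocity of
the preceding one.  Reverse integration is anchored at the forward end
value, the two are blended with weight ``alpha``, and a linear
boundary-condition ramp removes the residual endpoint error ``Ev``,
estimated as the gap between the blended endpoint and the phase mean (a
zero-velocity endpoint cannot be assumed for a lumbar-mounted sensor).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .events import StepPhases
from .filters import INTEGRATION_LP_CUTOFF, lowpass

__all__ = [
    "PhaseVelocity",
    "DriftCorrection",
    "prefilter_acc",
    "integrate_forward",
    "integrate_reverse",
    "blend",
    "estimate_ev",
    "correct_drift",
    "phase_velocity_pipeline",
]

DEFAULT_ALPHA = 0.5
END_WINDOW_SAMPLES = 3  # half-width of the endpoint-velocity averaging window


@dataclass
class PhaseVelocity:
    """Velocity reconstruction of one phase (E1 or E2) of one step."""

    t: np.ndarray
    v_direct: np.ndarray
    v_inverse: np.ndarray
    v_combined: np.ndarray
    v_corrected: np.ndarray
    v_mean: float
    phase: str  # "E1" | "E2"
    step_index: int
    ok: bool = True


@dataclass
class DriftCorrection:
    """Linear ramp correction distributing the velocity error Ev over [t0, tf]."""

    Ev: float
    t0: float
    tf: float

    def __post_init__(self) -> None:
        if self.tf <= self.t0:
            raise ValueError("degenerate correction interval (tf <= t0)")


def prefilter_acc(acc_ap: np.ndarray, fs: float, cutoff_hz: float = INTEGRATION_LP_CUTOFF) -> np.ndarray:
    """Second-order zero-phase low-pass (3.5 Hz) applied before integration."""
    return lowpass(acc_ap, fs, cutoff_hz, order=2)


def integrate_forward(acc: np.ndarray, fs: float, v0: float = 0.0) -> np.ndarray:
    """Cumulative trapezoidal integration with ``v[0] = v0``."""
    acc = np.asarray(acc, dtype=float)
    if acc.size < 2:
        raise ValueError("phase must contain at least 2 samples")
    return v0 + cumulative_trapezoid(acc, dx=1.0 / fs, initial=0.0)


def integrate_reverse(acc: np.ndarray, fs: float, v_end: float) -> np.ndarray:
    """Backward cumulative trapezoidal integration anchored at ``v[-1] = v_end``."""
    acc = np.asarray(acc, dtype=float)
    if acc.size < 2:
        raise ValueError("phase must contain at least 2 samples")
    fwd = cumulative_trapezoid(acc, dx=1.0 / fs, initial=0.0)
    return v_end - (fwd[-1] - fwd)


def blend(v_direct: np.ndarray, v_inverse: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Pointwise convex combination ``alpha*v_direct + (1-alpha)*v_inverse``."""
    v_direct = np.asarray(v_direct, dtype=float)
    v_inverse = np.asarray(v_inverse, dtype=float)
    if v_direct.shape != v_inverse.shape:
        raise ValueError("direct and inverse velocity profiles differ in length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * v_direct + (1.0 - alpha) * v_inverse


def estimate_ev(v_combined: np.ndarray) -> float:
    """Endpoint velocity error: blended endpoint minus the phase mean.

    The unknown true final velocity is approximated by the phase mean of
    the blended profile, so ``Ev = v[-1] - mean(v)``; it vanishes for
    constant velocity and drives the corrected endpoint onto the mean.
    """
    v = np.asarray(v_combined, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity profile")
    return float(v[-1] - v.mean())


def correct_drift(v_combined: np.ndarray, t: np.ndarray, corr: DriftCorrection) -> np.ndarray:
    """Subtract the linear ramp ``(t - t0)/(tf - t0) * Ev`` from the profile."""
    v = np.asarray(v_combined, dtype=float)
    t = np.asarray(t, dtype=float)
    if v.shape != t.shape:
        raise ValueError("velocity and time arrays differ in length")
    ramp = (t - corr.t0) / (corr.tf - corr.t0)
    return v - ramp * corr.Ev


def phase_velocity_pipeline(
    acc_ap: np.ndarray,
    phases: list[StepPhases],
    fs: float,
    alpha: float = DEFAULT_ALPHA,
    correct: bool = True,
    anchor_idx: int | None = None,
) -> list[PhaseVelocity]:
    """Reconstruct per-phase velocity profiles for a segmented trial.

    ``acc_ap`` must already be pre-filtered (see :func:`prefilter_acc`).
    Forward integration runs continuously from the anchor contact (v = 0;
    by default the first phase boundary, but the caller should pass the
    trial's first detected contact — the instant the method takes as a
    standstill) through the last phase, which realizes the
    initial-condition chaining exactly even across dropped steps; each
    phase is then sliced out, reverse integration anchored at its forward
    end value, blended, and drift-corrected.  A phase producing non-finite
    values is flagged (``ok=False``) rather than aborting the trial;
    ``correct=False`` disables the ramp correction (diagnostic use).
    """
    acc = np.asarray(acc_ap, dtype=float)
    if not phases:
        return []
    anchor = phases[0].i_ic if anchor_idx is None else int(anchor_idx)
    if anchor > phases[0].i_ic:
        raise ValueError("anchor contact must not lie after the first phase")
    i_stop = phases[-1].i_ic_next
    if anchor < 0 or i_stop >= acc.size:
        raise ValueError("phase boundaries outside the signal")
    # integrate over a slightly extended window so sub-sample phase
    # boundaries can be interpolated at either end
    lo = max(anchor - 2, 0)
    hi = min(i_stop + 2, acc.size - 1)
    grid = np.arange(lo, hi + 1)
    v_grid = cumulative_trapezoid(acc[lo : hi + 1], dx=1.0 / fs, initial=0.0)
    v_grid = v_grid - v_grid[anchor - lo]  # zero velocity at the anchor contact
    d_grid = cumulative_trapezoid(v_grid, dx=1.0 / fs, initial=0.0)

    out: list[PhaseVelocity] = []
    for k, ph in enumerate(phases):
        for name, i0, i1, f0, f1 in (
            ("E1", ph.i_ic, ph.i_ms, ph.f_ic, ph.f_ms),
            ("E2", ph.i_ms, ph.i_ic_next, ph.f_ms, ph.f_ic_next),
        ):
            t = np.arange(i0, i1 + 1) / fs
            v_dir = v_grid[i0 - lo : i1 - lo + 1].copy()
            v_inv = integrate_reverse(acc[i0 : i1 + 1], fs, v_end=float(v_dir[-1]))
            v_com = blend(v_dir, v_inv, alpha)
            if correct:
                ev = estimate_ev(v_com)
                v_cor = correct_drift(v_com, t, DriftCorrection(Ev=ev, t0=t[0], tf=t[-1]))
            else:
                v_cor = v_com.copy()
            ok = bool(np.all(np.isfinite(v_cor)))
            # scalar phase statistics on the sub-sample refined window:
            # the time-averaged blended velocity, the interpolated endpoint,
            # and the continuous-time effect of the ramp correction
            # (mean(v - ramp*Ev) = mean(v) - Ev/2)
            duration = (f1 - f0) / fs
            mean_com = float(np.interp(f1, grid, d_grid) - np.interp(f0, grid, d_grid)) / duration
            if correct:
                # endpoint velocity from a short symmetric time-average so
                # the drift estimate is insensitive to sub-sample boundary
                # skew and to the gait wave's odd symmetry about the event
                w = min(END_WINDOW_SAMPLES, (f1 - f0) / 2.0, grid[-1] - f1)
                if w >= 1.0:
                    v_end = float(
                        np.interp(f1 + w, grid, d_grid) - np.interp(f1 - w, grid, d_grid)
                    ) / (2.0 * w / fs)
                else:
                    v_end = float(np.interp(f1, grid, v_grid))
                ev_frac = v_end - mean_com
                v_mean = mean_com - 0.5 * ev_frac
            else:
                v_mean = mean_com
            out.append(
                PhaseVelocity(
                    t=t,
                    v_direct=v_dir,
                    v_inverse=v_inv,
                    v_combined=v_com,
                    v_corrected=v_cor,
                    v_mean=v_mean if ok else float("nan"),
                    phase=name,
                    step_index=k,
                    ok=ok,
                )
            )
    return out
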