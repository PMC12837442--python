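"""Synthetic lower-back IMU gait signals with exact ground truth.

The generator builds a forward center-of-mass velocity trajectory from a
parameterized kinematic gait plan and differentiates it analytically, so
the emitted anteroposterior acceleration is exactly consistent with the
trajectory and the ground-truth step lengths are the trajectory's own
displacement integrals (plus the pelvic projection, using the same sign
convention as the estimation model).  Signal phenomenology mirrors what a
sacral sensor records during level walking:

* the velocity carries a step-frequency oscillation whose deceleration
  extreme falls exactly at each initial contact, so the band-limited
  acceleration shows the characteristic contact valley;
* a short derivative-of-Gaussian impact transient (a momentary velocity dip
  of ~60 ms) is locked to each contact, its amplitude a proxy for heel
  strike sharpness;
* pelvic yaw oscillates at stride frequency, phased so the vertical angular
  velocity just after a left-stance contact is positive (pelvis swinging
  toward the right);
* roll oscillates at stride frequency with an extremum at every mid-stance;
* left/right asymmetry is injected as a stride-phase speed modulation
  (length ratio) and per-side step durations (timing ratio).

Two regimes are produced.  ``initiation=True`` (the default) emulates a
walking trial recorded from standstill: quiet standing, an anticipatory
weight-shift sway that brakes to a dead stop at the first contact (the
velocity is exactly zero in a ±40 ms plateau around it), acceleration to
steady gait over two steps, and symmetric termination.  This is the regime
the velocity-integration stage assumes, since it anchors the first braking
phase at zero velocity.  ``initiation=False`` produces steady-state walking
spanning the whole record (the subject already walking at record start),
which is the appropriate input for isolated event-detection validation; in
that regime every oscillation period in the record is a true step and is
listed in the ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import DEFAULT_PELVIC_SIGN
from .signals import ImuRecording, SubjectAnthropometrics, euler_to_quat

__all__ = ["GaitScenario", "GroundTruth", "simulate", "scenario_presets"]

IMPACT_SIGMA_S = 0.010  # Gaussian width of the contact velocity dip (~40 ms support)
IMPACT_DIP_MPS = 0.04  # velocity dip depth (m/s) at impact_sharpness = 1
IMPACT_LAG_S = 0.015  # delay of the loading-response transient after contact
YAW_PHASE_LEAD_RAD = 0.35  # stride-phase lead of the yaw wave; keeps the
# post-contact vertical angular velocity clearly signed
APA_PLATEAU_PRE_S = 0.05  # zero-velocity plateau before the first contact
APA_PLATEAU_POST_S = 0.05  # zero-velocity plateau after the first contact
APA_DROP_S = 0.30  # duration of each braking ramp flanking the plateau; slow
# enough to pass the integration pre-filter undistorted
APA_RISE_S = 1.4  # duration of the slow anticipatory weight-shift sway


def _default_anthro() -> SubjectAnthropometrics:
    return SubjectAnthropometrics(lp_right=0.92, lp_left=0.92, rp=0.15)


@dataclass
class GaitScenario:
    """Parameter set defining one synthetic walking trial."""

    n_steps: int = 16
    cadence: float = 1.8  # steps/s
    mean_speed: float = 1.3  # m/s
    speed_ripple: float = 0.12  # within-step velocity oscillation, fraction of mean speed
    yaw_amp_deg: float = 8.0
    roll_amp_deg: float = 4.0
    asym_len: float = 0.0  # left/right step-length ratio - 1
    asym_time: float = 0.0  # left/right step-duration ratio - 1 (split symmetrically)
    impact_sharpness: float = 1.0
    noise_acc: float = 0.15  # m/s^2 white noise on accelerations
    noise_gyro: float = 0.02  # rad/s white noise on angular velocity
    noise_yaw_deg: float = 0.5  # degrees white noise on orientation angles
    fs: float = 100.0
    seed: int = 0
    anthro: SubjectAnthropometrics = field(default_factory=_default_anthro)
    initiation: bool = True

    def __post_init__(self) -> None:
        if not 0.5 <= self.cadence <= 4.0:
            raise ValueError("cadence outside the physiologic range [0.5, 4] steps/s")
        if self.mean_speed <= 0:
            raise ValueError("mean speed must be positive")
        if abs(self.asym_len) >= 0.5 or abs(self.asym_time) >= 0.5:
            raise ValueError("asymmetry fractions must lie in (-0.5, 0.5)")
        if not 0 <= self.yaw_amp_deg < 90:
            raise ValueError("yaw amplitude must lie in [0, 90) degrees")
        if self.n_steps < 5:
            raise ValueError("need at least 5 steps for a meaningful trial")
        if self.fs <= 0 or self.speed_ripple < 0:
            raise ValueError("invalid sampling rate or ripple")


@dataclass
class GroundTruth:
    """Exact per-trial bookkeeping of the generative trajectory."""

    ic_times: np.ndarray  # one per contact, seconds (recording clock)
    ic_sides: list[str]
    ms_times: np.ndarray  # one per step
    step_lengths: np.ndarray  # m, displacement integral + pelvic projection
    step_sides: list[str]
    step_displacement: np.ndarray  # m, pure trajectory integral per step
    step_pelvic: np.ndarray  # m, signed pelvic contribution per step
    phase_velocities: np.ndarray  # (n_steps, 2) mean velocity of E1/E2
    t: np.ndarray
    v_true: np.ndarray  # noise-free forward velocity at the samples
    yaw_true: np.ndarray  # noise-free pelvic yaw, degrees
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.step_lengths <= 0):
            raise ValueError("generated a non-positive true step length")


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Quintic smoothstep 0 -> 1 over [t0, t1]; returns (value, derivative).

    C2-continuous at both ends, so speed ramps leak almost nothing into the
    1-2 Hz band the event detector works in.
    """
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    s = x**3 * (10.0 - 15.0 * x + 6.0 * x**2)
    ds = 30.0 * x**2 * (1.0 - x) ** 2 / (t1 - t0)
    ds[(t < t0) | (t > t1)] = 0.0
    return s, ds


def _step_plan(sc: GaitScenario) -> tuple[np.ndarray, list[str], int]:
    """Contact times (relative, first at 0), sides, and index of the first
    requested contact (steady trials carry extra warm-up steps)."""
    dur = {
        "left": (1.0 + sc.asym_time) / sc.cadence,
        "right": (1.0 - sc.asym_time) / sc.cadence,
    }
    # snap durations to the sample grid so contacts fall on samples exactly
    dur = {k: round(v * sc.fs) / sc.fs for k, v in dur.items()}
    extra = 0 if sc.initiation else 3  # steady trials extend the gait cycle
    n_ic = sc.n_steps + 1 + 2 * extra
    sides = [("left", "right")[k % 2] for k in range(n_ic)]
    times = np.zeros(n_ic)
    for k in range(1, n_ic):
        times[k] = times[k - 1] + dur[sides[k - 1]]
    return times, sides, extra


def _stride_phase(t: np.ndarray, ic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stride phase (pi per step, 0 at the first listed left contact) and
    its rate.

    A monotone C1 interpolant through the contact knots keeps the phase
    rate continuous when left/right step durations differ (a rate jump at
    the contacts would put a spurious discontinuity into the acceleration
    exactly at the event the detector looks for).  With equal durations it
    reduces to the linear phase.  Linear extrapolation with the end slopes
    extends the phase beyond the planned contacts.
    """
    from scipy.interpolate import CubicSpline

    knots = np.pi * np.arange(ic.size)
    interp = CubicSpline(ic, knots, bc_type='natural', extrapolate=False)
    dinterp = interp.derivative()
    psi = interp(t)
    dpsi = dinterp(t)
    before = t < ic[0]
    after = t > ic[-1]
    slope0 = np.pi / (ic[1] - ic[0])
    slope1 = np.pi / (ic[-1] - ic[-2])
    psi[before] = knots[0] + (t[before] - ic[0]) * slope0
    dpsi[before] = slope0
    psi[after] = knots[-1] + (t[after] - ic[-1]) * slope1
    dpsi[after] = slope1
    return psi, dpsi


def simulate(scenario: GaitScenario) -> tuple[ImuRecording, GroundTruth]:
    """Generate one trial: a validated recording plus its ground truth."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    fs, dt = sc.fs, 1.0 / sc.fs
    ic_rel, sides, extra = _step_plan(sc)
    t_mean = 1.0 / sc.cadence

    if sc.initiation:
        lead = round(2.0 * fs) * dt
        tail = 2.0
        t0, t_end = 0.0, lead + ic_rel[-1] + tail
        ic_t = lead + ic_rel
    else:
        # start/end the record three quarter step periods from a contact so
        # the band-limited wave meets the filter's reflective padding at a
        # zero-crossing (no boundary transient on the oscillation) and the
        # first contact's preceding peak lies inside the record
        margin = round(0.75 * t_mean * fs) * dt
        t0 = -margin
        t_end = ic_rel[-1] + margin
        ic_t = ic_rel
    n = int(round((t_end - t0) * fs)) + 1
    t = t0 + np.arange(n) * dt

    psi, dpsi = _stride_phase(t, ic_t)
    phi, dphi = 2.0 * psi, 2.0 * dpsi

    # ---- speed envelope ------------------------------------------------
    if sc.initiation:
        ic0, icK = ic_t[0], ic_t[-1]
        # speed ramps are kept slow (content below the detection band) so
        # they do not distort the contact valleys of the first/last steps
        t_on = ic0 + 0.1
        s_up, ds_up = _smoothstep(t, t_on, t_on + 1.6 * t_mean)
        s_dn, ds_dn = _smoothstep(t, icK - 0.8 * t_mean, icK + 2.2 * t_mean)
        env = s_up * (1.0 - s_dn)
        denv = ds_up * (1.0 - s_dn) - s_up * ds_dn
        # the step oscillation starts after the initiation braking has
        # settled, so its onset does not drag the first contact valley
        t_osc = ic0 + APA_PLATEAU_POST_S + APA_DROP_S
        s_osc, ds_osc = _smoothstep(t, t_osc, t_osc + 1.2 * t_mean)
        env_osc = s_osc * (1.0 - s_dn)
        denv_osc = ds_osc * (1.0 - s_dn) - s_osc * ds_dn
    else:
        env = np.ones(n)
        denv = np.zeros(n)
        env_osc = env
        denv_osc = denv

    # stride-phase speed modulation realizing the requested length ratio:
    # left steps span psi in [0, pi] where sin(psi) >= 0
    x = sc.asym_len / (2.0 + sc.asym_len)
    a_v = 0.5 * np.pi * x
    mod = 1.0 + a_v * np.sin(psi)
    dmod = a_v * np.cos(psi) * dpsi
    v_base = sc.mean_speed * env * mod
    a_base = sc.mean_speed * (denv * mod + env * dmod)

    # ---- step-frequency oscillation (the contact valley generator) -----
    ripple = sc.speed_ripple * sc.mean_speed
    v_osc = -ripple * env_osc * np.sin(phi)
    a_osc = -ripple * (denv_osc * np.sin(phi) + env_osc * np.cos(phi) * dphi)

    # ---- contact impact transients -------------------------------------
    dip = IMPACT_DIP_MPS * sc.impact_sharpness
    # the initiation contact is a gentle foot placement from standstill: no
    # impact transient there (it would also break the zero-velocity anchor)
    imp_ics = ic_t[1:] if sc.initiation else ic_t
    # the loading-response transient peaks shortly after the contact itself
    dt_ic = t[None, :] - (imp_ics[:, None] + IMPACT_LAG_S)
    gauss = np.exp(-0.5 * (dt_ic / IMPACT_SIGMA_S) ** 2)
    v_imp = -dip * gauss.sum(axis=0)
    a_imp = -dip * (gauss * (-dt_ic / IMPACT_SIGMA_S**2)).sum(axis=0)

    # ---- gait-initiation sway (standstill-anchored trials only) --------
    v_apa = np.zeros(n)
    a_apa = np.zeros(n)
    if sc.initiation:
        h = float(np.clip(0.8 * sc.speed_ripple * sc.mean_speed, 0.07, 0.14))
        ic0 = ic_t[0]
        segs = [
            (+h, ic0 - APA_PLATEAU_PRE_S - APA_DROP_S - APA_RISE_S, ic0 - APA_PLATEAU_PRE_S - APA_DROP_S),
            (-h, ic0 - APA_PLATEAU_PRE_S - APA_DROP_S, ic0 - APA_PLATEAU_PRE_S),
            (-h, ic0 + APA_PLATEAU_POST_S, ic0 + APA_PLATEAU_POST_S + APA_DROP_S),
            (+h, ic0 + APA_PLATEAU_POST_S + APA_DROP_S + 0.05, ic0 + APA_PLATEAU_POST_S + APA_DROP_S + 2.05),
        ]
        for amp, a, b in segs:
            s, ds = _smoothstep(t, a, b)
            v_apa += amp * s
            a_apa += amp * ds

    v_true = v_base + v_osc + v_imp + v_apa
    acc_true = a_base + a_osc + a_imp + a_apa

    # ---- orientation ----------------------------------------------------
    yaw_true = -sc.yaw_amp_deg * env * np.cos(psi + YAW_PHASE_LEAD_RAD)
    roll_true = sc.roll_amp_deg * env * np.sin(psi)
    gyro_true = np.gradient(np.radians(yaw_true), dt)

    # ---- assemble the noisy recording -----------------------------------
    acc_ap = acc_true + rng.normal(0.0, sc.noise_acc, n)
    acc_v = 0.3 * np.abs(acc_true) * np.cos(2 * phi) + rng.normal(0.0, sc.noise_acc, n)
    acc_ml = 0.2 * np.ptp(acc_true) * env * np.cos(psi) + rng.normal(0.0, sc.noise_acc, n)
    gyro_vert = gyro_true + rng.normal(0.0, sc.noise_gyro, n)
    yaw_n = yaw_true + rng.normal(0.0, sc.noise_yaw_deg, n)
    roll_n = roll_true + rng.normal(0.0, sc.noise_yaw_deg, n)
    quat = euler_to_quat(roll_n, np.zeros(n), yaw_n)
    rec = ImuRecording(
        t=t,
        fs=fs,
        acc_ap=acc_ap,
        acc_v=acc_v,
        acc_ml=acc_ml,
        gyro_vert=gyro_vert,
        quat=quat,
    )

    # ---- ground truth ----------------------------------------------------
    disp = cumulative_trapezoid(v_true, dx=dt, initial=0.0)
    ic_idx = np.round((ic_t - t0) * fs).astype(int)
    ms_idx = np.round(((ic_t[:-1] + ic_t[1:]) / 2.0 - t0) * fs).astype(int)
    n_steps = ic_idx.size - 1
    lengths = np.empty(n_steps)
    displ = np.empty(n_steps)
    pelv = np.empty(n_steps)
    pv = np.empty((n_steps, 2))
    for k in range(n_steps):
        i0, im, i1 = ic_idx[k], ms_idx[k], ic_idx[k + 1]
        displ[k] = disp[i1] - disp[i0]
        d1 = yaw_true[im] - yaw_true[i0]
        d2 = yaw_true[i1] - yaw_true[im]
        pelv[k] = DEFAULT_PELVIC_SIGN * sc.anthro.rp * (
            np.tan(np.radians(d1)) + np.tan(np.radians(d2))
        )
        lengths[k] = displ[k] + pelv[k]
        pv[k, 0] = float(np.mean(v_true[i0 : im + 1]))
        pv[k, 1] = float(np.mean(v_true[im : i1 + 1]))
    truth = GroundTruth(
        ic_times=t[ic_idx],
        ic_sides=list(sides),
        ms_times=t[ms_idx],
        step_lengths=lengths,
        step_sides=list(sides[:-1]),
        step_displacement=displ,
        step_pelvic=pelv,
        phase_velocities=pv,
        t=t,
        v_true=v_true,
        yaw_true=yaw_true,
        fs=fs,
    )
    return rec, truth


def scenario_presets() -> dict[str, GaitScenario]:
    """Named scenarios spanning the gait phenotypes the pipeline targets.

    Amplitudes and rates are synthetic but physiologically plausible
    defaults; they are not measured cohort values.
    """
    return {
        "healthy_adult": GaitScenario(),
        "older_adult": GaitScenario(
            cadence=1.5, mean_speed=0.9, yaw_amp_deg=6.0, roll_amp_deg=3.5,
            speed_ripple=0.10, impact_sharpness=0.7,
        ),
        "asymmetric_mild": GaitScenario(
            asym_len=0.10, asym_time=0.04, yaw_amp_deg=10.0,
        ),
        "asymmetric_severe": GaitScenario(
            cadence=1.4, mean_speed=0.8, asym_len=0.25, asym_time=0.10,
            yaw_amp_deg=14.0, impact_sharpness=0.4, speed_ripple=0.18,
        ),
        "shuffling": GaitScenario(
            cadence=1.4, mean_speed=0.6, speed_ripple=0.05, impact_sharpness=0.1,
            yaw_amp_deg=3.0, roll_amp_deg=1.5,
        ),
    }
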