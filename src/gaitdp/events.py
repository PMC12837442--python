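"""Gait event detection: initial contacts, mid-stances, stance-limb labels.

At each initial contact (IC) the pelvis decelerates sharply, which appears
as a valley in the anteroposterior acceleration once the signal is reduced
to its fundamental locomotion wave (0.5 Hz high-pass then 1.8 Hz low-pass).
Mid-stance (MS) shows up as alternating extrema of the frontal-plane roll
trace, and the stance limb is read off the sign of the vertical angular
velocity immediately after the contact: the pelvis swinging toward the
right (positive) means the left leg is in support, and vice versa.

Consecutive ICs bracketing exactly one MS define one step, split into a
braking phase E1 (IC to MS) and a propulsion phase E2 (MS to next IC).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .filters import HP_CUTOFF, HP_ORDER, LP_CUTOFF, LP_ORDER, highpass, lowpass

__all__ = [
    "GaitEvents",
    "StepPhases",
    "detect_initial_contacts",
    "detect_midstance",
    "assign_side",
    "segment_phases",
]

REFRACTORY_S = 0.25  # minimal IC spacing; cadence above 4 steps/s is non-physiologic
THRESHOLD_FRACTION = 0.22  # acceptance fraction of the local median valley depth
THRESHOLD_WINDOW_S = 5.0  # sliding window for the local median
GLOBAL_FLOOR_FRACTION = 0.15  # floor relative to the trial-wide upper-quartile peak
VALLEY_REFINE_SAMPLES = 4  # final valley localization window, +/- samples
REFINE_LP_CUTOFF = 9.0  # Hz, broader band used for the final valley localization
SIDE_AVG_SAMPLES = 4  # gyro samples averaged after the contact for limb labelling


@dataclass
class GaitEvents:
    """Detected events of one trial (sample indices at rate ``fs``)."""

    ic_idx: np.ndarray
    ms_idx: np.ndarray
    side: list[str]
    fs: float
    # sub-sample refined positions (float samples); default to the indices
    ic_pos: np.ndarray | None = None
    ms_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ic_idx = np.asarray(self.ic_idx, dtype=int)
        self.ms_idx = np.asarray(self.ms_idx, dtype=int)
        if self.ic_pos is None:
            self.ic_pos = self.ic_idx.astype(float)
        else:
            self.ic_pos = np.asarray(self.ic_pos, dtype=float)
            if self.ic_pos.shape != self.ic_idx.shape:
                raise ValueError("ic_pos must match ic_idx")
        if self.ms_pos is None:
            self.ms_pos = self.ms_idx.astype(float)
        else:
            self.ms_pos = np.asarray(self.ms_pos, dtype=float)
            if self.ms_pos.shape != self.ms_idx.shape:
                raise ValueError("ms_pos must match ms_idx")
        if np.any(np.diff(self.ic_idx) <= 0):
            raise ValueError("initial-contact indices must be strictly increasing")
        if len(self.side) != self.ic_idx.size:
            raise ValueError("one side label per initial contact required")
        sides = np.asarray(self.side)
        if sides.size >= 2 and np.any(sides[1:] == sides[:-1]):
            warnings.warn("side labels do not strictly alternate", stacklevel=2)

    @property
    def ic_times(self) -> np.ndarray:
        return self.ic_idx / self.fs

    @property
    def ms_times(self) -> np.ndarray:
        return self.ms_idx / self.fs


@dataclass
class StepPhases:
    """One step delimited by two contacts, split at mid-stance."""

    i_ic: int
    i_ms: int
    i_ic_next: int
    side: str
    fs: float
    analyzed: bool = True  # False for the first/last-two steps, excluded from stats
    # sub-sample boundary positions (float samples); default to the indices
    f_ic: float | None = None
    f_ms: float | None = None
    f_ic_next: float | None = None

    def __post_init__(self) -> None:
        if not (self.i_ic < self.i_ms < self.i_ic_next):
            raise ValueError("phase boundaries must satisfy ic < ms < next ic")
        if self.f_ic is None:
            self.f_ic = float(self.i_ic)
        if self.f_ms is None:
            self.f_ms = float(self.i_ms)
        if self.f_ic_next is None:
            self.f_ic_next = float(self.i_ic_next)
        if not (self.f_ic < self.f_ms < self.f_ic_next):
            raise ValueError("refined boundaries must satisfy ic < ms < next ic")

    @property
    def t_ic(self) -> float:
        return self.f_ic / self.fs

    @property
    def t_ms(self) -> float:
        return self.f_ms / self.fs

    @property
    def t_ic_next(self) -> float:
        return self.f_ic_next / self.fs

    @property
    def T_E1(self) -> float:
        return (self.f_ms - self.f_ic) / self.fs

    @property
    def T_E2(self) -> float:
        return (self.f_ic_next - self.f_ms) / self.fs


def _parabolic_delta(y: np.ndarray, v: int) -> float:
    """Sub-sample offset of the extremum of the parabola through
    ``y[v-1], y[v], y[v+1]``; zero when the fit is degenerate."""
    if not 0 < v < y.size - 1:
        return 0.0
    denom = y[v - 1] - 2.0 * y[v] + y[v + 1]
    if abs(denom) < 1e-15:
        return 0.0
    return float(np.clip(0.5 * (y[v - 1] - y[v + 1]) / denom, -1.0, 1.0))


def _snap_consistent(positions: list[tuple[int, float]]) -> list[int]:
    """Round refined event positions to the sample grid consistently.

    The sub-sample offsets share a systematic component (the event
    waveform's shape is common to all steps of a trial); rounding each
    event independently lets that common offset hover around a half-sample
    boundary and flip neighbouring events by one sample.  Removing the
    median offset before rounding and re-applying it as a whole-sample
    shift keeps the quantization consistent across the trial.
    """
    if not positions:
        return []
    deltas = np.array([d for _, d in positions])
    common = float(np.median(deltas))
    shift = int(round(common))
    return [int(round(v + d - common)) + shift for v, d in positions]


def _zero_crossings(d: np.ndarray, direction: str) -> np.ndarray:
    """Indices i where d changes sign between i and i+1."""
    s = np.sign(d)
    if direction == "falling":
        idx = np.flatnonzero((s[:-1] > 0) & (s[1:] <= 0))
    else:
        idx = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
    return idx + 1


def detect_initial_contacts(
    acc_ap: np.ndarray,
    fs: float,
    hp_cutoff: float = HP_CUTOFF,
    lp_cutoff: float = LP_CUTOFF,
    hp_order: int = HP_ORDER,
    lp_order: int = LP_ORDER,
    return_positions: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Detect initial contacts as deceleration valleys of the filtered signal.

    Pipeline: zero-phase high-pass (offset removal) then low-pass (isolate
    the fundamental wave); the derivative's zero-crossings yield candidate
    peaks and valleys, and only valleys preceded by a peak are considered
    (the step's acceleration maximum reliably precedes the contact
    deceleration).  An adaptive depth threshold — a fraction of the median
    candidate depth within a sliding window, floored at a fraction of the
    trial-wide upper-quartile depth so that quiet standing segments do not
    generate events — keeps only genuine steps.  Each accepted valley is
    then localized within +/- 4 samples on a broader-band version of the
    signal (narrow-band filtering skews valley positions when left/right
    step periods differ), refined to sub-sample precision with a parabolic
    vertex fit, and quantized to the grid consistently across the trial.
    A refractory period enforces physiologic step spacing.

    With ``return_positions=True`` the sub-sample positions (float samples)
    are returned alongside the integer indices.
    """
    x = np.asarray(acc_ap, dtype=float)
    if x.size < 3 * fs:
        raise ValueError("need at least 3 s of signal for contact detection")
    hp = highpass(x, fs, hp_cutoff, hp_order)
    y = lowpass(hp, fs, lp_cutoff, lp_order)
    # the final +/-4-sample valley localization runs on a broader band:
    # the narrow fundamental band can skew valley positions when left and
    # right step periods differ (a frequency-modulated wave), while the
    # wider band keeps the contact minimum in place
    y_ref = lowpass(hp, fs, max(REFINE_LP_CUTOFF, lp_cutoff), order=2)
    empty = (np.array([], dtype=int), np.array([])) if return_positions else np.array([], dtype=int)
    if np.ptp(y) < 1e-12:
        warnings.warn("flat signal: no initial contacts found", stacklevel=2)
        return empty
    dy = np.diff(y)
    peaks = _zero_crossings(dy, "falling")
    valleys = _zero_crossings(dy, "rising")
    if peaks.size == 0 or valleys.size == 0:
        warnings.warn("no candidate events found", stacklevel=2)
        return empty
    # each candidate valley must follow a peak (the step's acceleration
    # maximum reliably precedes the contact deceleration)
    valleys = valleys[valleys > peaks[0]]

    depths = -y[valleys]  # positive for genuine deceleration valleys
    pos = depths[depths > 0]
    floor = GLOBAL_FLOOR_FRACTION * (np.percentile(pos, 75) if pos.size else 0.0)
    half_w = THRESHOLD_WINDOW_S / 2.0
    valley_t = valleys / fs
    accepted: list[tuple[int, float]] = []
    for i, v in enumerate(valleys):
        near = np.abs(valley_t - valley_t[i]) <= half_w
        local = np.median(np.abs(depths[near]))
        thr = max(THRESHOLD_FRACTION * local, floor)
        if depths[i] < thr:
            continue
        v = int(v)
        lo = max(v - VALLEY_REFINE_SAMPLES, 0)
        hi = min(v + VALLEY_REFINE_SAMPLES + 1, y.size)
        v = lo + int(np.argmin(y_ref[lo:hi]))
        accepted.append((v, _parabolic_delta(y_ref, v)))

    ics: list[int] = []
    pos: list[float] = []
    refractory = int(round(REFRACTORY_S * fs))
    for (raw_v, delta), v in zip(accepted, _snap_consistent(accepted)):
        v = int(np.clip(v, 0, y.size - 1))
        if ics and v - ics[-1] < refractory:
            if y_ref[v] < y_ref[ics[-1]]:  # keep the deeper valley
                ics[-1] = v
                pos[-1] = raw_v + delta
            continue
        if not ics or v > ics[-1]:
            ics.append(v)
            pos.append(raw_v + delta)
    if not ics:
        warnings.warn("no initial contacts passed the amplitude threshold", stacklevel=2)
    if return_positions:
        return np.asarray(ics, dtype=int), np.asarray(pos)
    return np.asarray(ics, dtype=int)


def detect_midstance(
    roll_deg: np.ndarray,
    fs: float,
    hp_cutoff: float = HP_CUTOFF,
    lp_cutoff: float = LP_CUTOFF,
    return_positions: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Detect mid-stances as alternating extrema of the roll trace.

    The roll signal is zero-phase high-passed to centre it on zero (and
    low-passed to its gait band so sensor noise does not seed spurious
    extrema), then its derivative's zero-crossings locate maxima and
    minima; both polarities are mid-stance events (one per stance side).
    Small-amplitude extrema (below a fraction of the median extremum
    magnitude) are rejected.
    """
    x = np.asarray(roll_deg, dtype=float)
    if x.size < 3 * fs:
        raise ValueError("need at least 3 s of signal for mid-stance detection")
    empty = (np.array([], dtype=int), np.array([])) if return_positions else np.array([], dtype=int)
    y = lowpass(highpass(x, fs, hp_cutoff), fs, lp_cutoff)
    if np.ptp(y) < 1e-9:
        return empty
    dy = np.diff(y)
    ext = np.sort(np.concatenate([_zero_crossings(dy, "falling"), _zero_crossings(dy, "rising")]))
    if ext.size == 0:
        return empty
    mags = np.abs(y[ext])
    floor = GLOBAL_FLOOR_FRACTION * np.percentile(mags, 75)
    thr = max(THRESHOLD_FRACTION * np.median(mags), floor, 1e-9)
    keep = ext[mags >= thr]
    # maxima and minima are refined separately (their parabola offsets are
    # mirrored), then snapped with a trial-consistent quantization
    refined = [(int(e), _parabolic_delta(np.abs(y), int(e))) for e in keep]
    # enforce a refractory spacing, keeping the larger extremum
    out: list[int] = []
    pos: list[float] = []
    refractory = int(round(0.2 * fs))
    for (raw_e, delta), e in zip(refined, _snap_consistent(refined)):
        e = int(np.clip(e, 0, y.size - 1))
        if out and e - out[-1] < refractory:
            if abs(y[e]) > abs(y[out[-1]]):
                out[-1] = int(e)
                pos[-1] = raw_e + delta
            continue
        out.append(int(e))
        pos.append(raw_e + delta)
    if return_positions:
        return np.asarray(out, dtype=int), np.asarray(pos)
    return np.asarray(out, dtype=int)


def assign_side(
    gyro_vert: np.ndarray,
    ic_idx: np.ndarray,
    invert: bool = False,
    zero_tol: float = 1e-9,
) -> list[str]:
    """Label the stance limb at each contact from vertical angular velocity.

    The angular velocity is averaged over the few samples following the
    contact; a positive mean (pelvis rotating toward the right) labels left
    stance, a negative mean right stance.  Zero means are labelled by
    alternation with their neighbours; ``invert`` accommodates sensors
    mounted upside-down.
    """
    g = np.asarray(gyro_vert, dtype=float)
    ic_idx = np.asarray(ic_idx, dtype=int)
    if ic_idx.size and (ic_idx.min() < 0 or ic_idx.max() >= g.size):
        raise ValueError("contact index outside signal bounds")
    raw: list[str] = []
    for i in ic_idx:
        seg = g[i : min(i + SIDE_AVG_SAMPLES, g.size)]
        m = float(np.mean(seg)) * (-1.0 if invert else 1.0)
        if m > zero_tol:
            raw.append("left")
        elif m < -zero_tol:
            raw.append("right")
        else:
            raw.append("ambiguous")
    # resolve ambiguous labels by alternation with resolved neighbours
    other = {"left": "right", "right": "left"}
    for i, lab in enumerate(raw):
        if lab != "ambiguous":
            continue
        if i > 0 and raw[i - 1] in other:
            raw[i] = other[raw[i - 1]]
        elif i + 1 < len(raw) and raw[i + 1] in other:
            raw[i] = other[raw[i + 1]]
    # isolated leading/trailing ambiguity: fall back to the majority pattern
    for i, lab in enumerate(raw):
        if lab == "ambiguous":
            raw[i] = "left" if i % 2 == 0 else "right"
    return raw


def segment_phases(events: GaitEvents, trim_steps: int = 2) -> list[StepPhases]:
    """Build per-step phases from detected events.

    One step is produced for each consecutive contact pair with exactly one
    mid-stance strictly between the two contacts; pairs with zero or several
    interior mid-stances are dropped with a warning.  The first and last
    ``trim_steps`` steps are flagged ``analyzed=False`` (gait initiation and
    termination are excluded from error statistics).
    """
    if events.ic_idx.size < 2:
        raise ValueError("need at least two initial contacts to segment steps")
    steps: list[StepPhases] = []
    dropped = 0
    for k in range(events.ic_idx.size - 1):
        i0, i1 = int(events.ic_idx[k]), int(events.ic_idx[k + 1])
        inside = (events.ms_idx > i0) & (events.ms_idx < i1)
        if int(inside.sum()) != 1:
            dropped += 1
            continue
        j = int(np.flatnonzero(inside)[0])
        steps.append(
            StepPhases(
                i_ic=i0,
                i_ms=int(events.ms_idx[j]),
                i_ic_next=i1,
                side=events.side[k],
                fs=events.fs,
                f_ic=float(events.ic_pos[k]),
                f_ms=float(events.ms_pos[j]),
                f_ic_next=float(events.ic_pos[k + 1]),
            )
        )
    if dropped:
        warnings.warn(f"dropped {dropped} contact pair(s) without a unique mid-stance", stacklevel=2)
    n = len(steps)
    for j, s in enumerate(steps):
        if j < trim_steps or j >= n - trim_steps:
            s.analyzed = False
    return steps
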