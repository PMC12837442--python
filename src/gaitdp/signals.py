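"""Domain types, file readers/writers and orientation conversion.

The package works on synchronized time series from a single inertial
measurement unit worn over the sacrum: three-axis acceleration, angular
velocity about the gravity-aligned vertical axis, and the orientation
quaternion stream produced by the sensor's onboard fusion.  Axes are named
semantically (anteroposterior / vertical / mediolateral); a column *dialect*
maps whatever layout a given sensor file uses onto those names, so the rest
of the pipeline never sees raw axis letters.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "ImuRecording",
    "SubjectAnthropometrics",
    "EulerAngles",
    "DEFAULT_DIALECT",
    "read_recording",
    "read_anthropometrics",
    "quat_to_euler",
    "euler_to_quat",
    "write_steps",
    "read_steps",
]

STANDARD_GRAVITY = 9.81  # m/s^2


class RecordingError(ValueError):
    """Raised when an input file cannot be validated as an IMU recording."""


@dataclass
class ImuRecording:
    """Uniformly sampled IMU streams from a lower-back sensor.

    Attributes
    ----------
    t : seconds, uniformly sampled.
    fs : sampling rate in Hz (nominally 100 Hz).
    acc_ap, acc_v, acc_ml : accelerations in m/s^2 along the anteroposterior,
        vertical and mediolateral body axes.
    gyro_vert : angular velocity about the vertical axis, rad/s.
    quat : unit quaternions, scalar-first ``(w, x, y, z)``, shape (n, 4).
    roll_deg, yaw_deg : optional pre-extracted orientation angles, degrees.
    """

    t: np.ndarray
    fs: float
    acc_ap: np.ndarray
    acc_v: np.ndarray
    acc_ml: np.ndarray
    gyro_vert: np.ndarray
    quat: np.ndarray
    roll_deg: np.ndarray | None = None
    yaw_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fs = float(self.fs)
        for name in ("acc_ap", "acc_v", "acc_ml", "gyro_vert"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.quat = np.asarray(self.quat, dtype=float)
        if self.fs <= 0:
            raise RecordingError("sampling rate must be positive")
        n = self.t.size
        if n < 2:
            raise RecordingError("recording too short: need at least 2 samples")
        for name in ("acc_ap", "acc_v", "acc_ml", "gyro_vert"):
            if getattr(self, name).shape != (n,):
                raise RecordingError(f"channel {name!r} length differs from time base")
        if self.quat.shape != (n, 4):
            raise RecordingError("quaternion stream must have shape (n, 4)")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9):
            raise RecordingError("time base is not uniform at the declared rate")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise RecordingError("quaternions deviate from unit norm beyond 1e-3")
        for name in ("roll_deg", "yaw_deg"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != (n,):
                    raise RecordingError(f"channel {name!r} length differs from time base")
                setattr(self, name, val)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def orientation(self) -> "EulerAngles":
        """Euler angles for the trial, preferring pre-extracted channels."""
        if self.roll_deg is not None and self.yaw_deg is not None:
            return EulerAngles(
                roll=self.roll_deg.copy(),
                pitch=np.zeros_like(self.roll_deg),
                yaw=self.yaw_deg.copy(),
            )
        return quat_to_euler(self.quat)


@dataclass
class SubjectAnthropometrics:
    """Per-side leg length and pelvic radius entering the step-length model.

    ``lp_*`` is the greater-trochanter-to-sole distance of each leg and
    ``rp`` the mid-sacrum-to-iliac-crest distance (the lever arm of the
    transverse pelvic rotation), all in metres.
    """

    lp_right: float
    lp_left: float
    rp: float
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        for name in ("lp_right", "lp_left", "rp", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rp >= min(self.lp_right, self.lp_left):
            warnings.warn(
                "pelvic radius is not smaller than leg length; "
                "check anthropometric units",
                stacklevel=2,
            )

    def leg_length(self, side: str) -> float:
        if side == "left":
            return self.lp_left
        if side == "right":
            return self.lp_right
        raise ValueError(f"unknown side {side!r}")


@dataclass
class EulerAngles:
    """Per-sample intrinsic Z-Y-X (yaw-pitch-roll) angles in degrees, unwrapped."""

    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray


def quat_to_euler(quat: np.ndarray) -> EulerAngles:
    """Convert scalar-first unit quaternions to unwrapped Euler angles.

    The decomposition is intrinsic Z-Y-X: yaw is the rotation about the
    gravity-aligned vertical axis, followed by pitch and roll.  Angles are
    unwrapped along the trial so that pelvic rotation traces are continuous.
    """
    quat = np.atleast_2d(np.asarray(quat, dtype=float))
    norms = np.linalg.norm(quat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("non-unit quaternion beyond 1e-3 tolerance")
    rot = Rotation.from_quat(quat / norms[:, None], scalar_first=True)
    yaw, pitch, roll = rot.as_euler("ZYX", degrees=True).T
    unwrap = lambda a: np.degrees(np.unwrap(np.radians(a)))
    return EulerAngles(roll=unwrap(roll), pitch=unwrap(pitch), yaw=unwrap(yaw))


def euler_to_quat(roll: np.ndarray, pitch: np.ndarray, yaw: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_to_euler`; angles in degrees, output scalar-first."""
    angles = np.column_stack([np.asarray(yaw, float), np.asarray(pitch, float), np.asarray(roll, float)])
    return Rotation.from_euler("ZYX", angles, degrees=True).as_quat(scalar_first=True)


# Default column mapping for trial CSV files.  ``accel_unit`` may be "m/s2"
# or "g"; ``quat_order`` states the component order in the file explicitly
# because sensor vendors disagree on it.
DEFAULT_DIALECT: dict = {
    "time": "t",
    "acc_ap": "az",
    "acc_v": "ay",
    "acc_ml": "ax",
    "gyro_vert": "gy",
    "quat": ["qw", "qx", "qy", "qz"],
    "quat_order": "wxyz",
    "accel_unit": "m/s2",
    "gyro_unit": "rad/s",
}


def read_recording(
    path: str | Path,
    dialect: Mapping | None = None,
    fs: float | None = None,
) -> ImuRecording:
    """Read a trial CSV into a validated :class:`ImuRecording`.

    Parameters
    ----------
    path : CSV file, one row per sample.
    dialect : column-map configuration (see :data:`DEFAULT_DIALECT`).
    fs : declared sampling rate; required if the dialect names no time column.

    Raises
    ------
    RecordingError
        On missing columns, non-uniform sampling (gaps larger than twice the
        sample interval), or files too short to process.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path)
    if len(df) < 2:
        raise RecordingError(f"{path}: file empty or too short ({len(df)} rows)")

    def col(name: str) -> np.ndarray:
        cname = d[name]
        if cname not in df.columns:
            raise RecordingError(f"{path}: missing column {cname!r} for channel {name!r}")
        return df[cname].to_numpy(dtype=float)

    if d.get("time") and d["time"] in df.columns:
        t = df[d["time"]].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise RecordingError(f"{path}: time column not strictly increasing")
        med = float(np.median(dt))
        if np.any(dt > 2.0 * med):
            raise RecordingError(f"{path}: non-uniform sampling, gap of {dt.max():.3g} s")
        if np.any(np.abs(dt - med) > 1e-6):
            raise RecordingError(f"{path}: non-uniform sampling")
        fs_eff = 1.0 / med
    elif fs is not None:
        fs_eff = float(fs)
        t = np.arange(len(df)) / fs_eff
    else:
        raise RecordingError(f"{path}: no time column and no declared sampling rate")

    quat_cols = d["quat"]
    for c in quat_cols:
        if c not in df.columns:
            raise RecordingError(f"{path}: missing quaternion column {c!r}")
    quat = df[list(quat_cols)].to_numpy(dtype=float)
    order = d.get("quat_order", "wxyz")
    perm = [order.index(ax) for ax in "wxyz"]
    quat = quat[:, perm]

    scale = STANDARD_GRAVITY if d.get("accel_unit") == "g" else 1.0
    gscale = np.pi / 180.0 if d.get("gyro_unit") in ("deg/s", "dps") else 1.0

    kwargs = {}
    for opt in ("roll_deg", "yaw_deg"):
        if d.get(opt) and d[opt] in df.columns:
            kwargs[opt] = df[d[opt]].to_numpy(dtype=float)

    # rebuild an exactly uniform time base from the validated rate
    t = t[0] + np.arange(len(df)) / fs_eff
    return ImuRecording(
        t=t,
        fs=fs_eff,
        acc_ap=col("acc_ap") * scale,
        acc_v=col("acc_v") * scale,
        acc_ml=col("acc_ml") * scale,
        gyro_vert=col("gyro_vert") * gscale,
        quat=quat,
        **kwargs,
    )


def read_anthropometrics(path: str | Path) -> SubjectAnthropometrics:
    """Read the JSON sidecar ``{lp_right, lp_left, rp[, g]}`` (metres)."""
    with open(path) as fh:
        data = json.load(fh)
    return SubjectAnthropometrics(
        lp_right=float(data["lp_right"]),
        lp_left=float(data["lp_left"]),
        rp=float(data["rp"]),
        g=float(data.get("g", STANDARD_GRAVITY)),
    )


STEP_COLUMNS = [
    "step_index",
    "side",
    "t_ic",
    "t_ms",
    "t_ic_next",
    "L_pendular_E1",
    "L_pendular_E2",
    "L_pelvic_E1",
    "L_pelvic_E2",
    "L_total",
]


def write_steps(steps: Sequence, path: str | Path) -> None:
    """Write per-step estimates to CSV (lossless round trip with read_steps)."""
    rows = []
    for s in steps:
        rows.append({c: getattr(s, c) for c in STEP_COLUMNS})
    if not rows:
        warnings.warn("writing an empty step table (header only)", stacklevel=2)
    df = pd.DataFrame(rows, columns=STEP_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_steps(path: str | Path) -> pd.DataFrame:
    """Read a step table written by :func:`write_steps`."""
    return pd.read_csv(path)
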