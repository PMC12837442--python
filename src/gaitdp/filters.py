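"""Filter design and application for the detection and integration paths.

Three filtering primitives are used downstream:

* zero-phase Butterworth high/low-pass chains (event detection and the
  pre-integration smoothing of anteroposterior acceleration),
* an FFT-bin high-pass for the pelvic yaw trace (offset and slow-drift
  removal without touching the gait band), and
* a wavelet-based estimate of the dominant locomotion band, used purely for
  quality control of the fixed cutoffs.

All Butterworth filters are applied forward-backward so detected event times
are not lag-shifted; the stated order is the design order of the single-pass
prototype.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "FilterSpec",
    "SpectralBand",
    "butterworth_filter",
    "highpass",
    "lowpass",
    "locomotion_band",
    "fft_bin_highpass",
]

# Defaults fixed for the event-detection and integration chains (Hz).
HP_CUTOFF = 0.5
LP_CUTOFF = 1.8
HP_ORDER = 4
LP_ORDER = 4
YAW_CUTOFF = 0.25
INTEGRATION_LP_CUTOFF = 3.5
EDGE_PAD_SECONDS = 2.0  # reflective padding to suppress boundary transients


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth high- or low-pass design."""

    kind: str  # "highpass" | "lowpass"
    order: int
    cutoff_hz: float

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order not in (2, 4):
            raise ValueError("filter order must be 2 or 4")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class SpectralBand:
    """Dominant locomotion band of an acceleration trace (QC only)."""

    f_lo: float
    f_hi: float
    dominant_f: float
    clear_peak: bool = True


def butterworth_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply a zero-phase (forward-backward) Butterworth filter.

    Zero-phase application preserves event timing; the output has the same
    length as the input.  Reflective padding of up to
    :data:`EDGE_PAD_SECONDS` keeps trial-boundary transients out of the
    analyzed interior.
    """
    x = np.asarray(x, dtype=float)
    if spec.cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz at or above Nyquist ({fs / 2} Hz)")
    if x.size <= 3 * spec.order:
        raise ValueError(f"signal too short ({x.size} samples) for order-{spec.order} filter")
    btype = "high" if spec.kind == "highpass" else "low"
    sos = butter(spec.order, spec.cutoff_hz, btype=btype, fs=fs, output="sos")
    padlen = min(int(EDGE_PAD_SECONDS * fs), x.size - 2)
    return sosfiltfilt(sos, x, padlen=padlen)


def highpass(x: np.ndarray, fs: float, cutoff_hz: float = HP_CUTOFF, order: int = HP_ORDER) -> np.ndarray:
    return butterworth_filter(x, FilterSpec("highpass", order, cutoff_hz), fs)


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float = LP_CUTOFF, order: int = LP_ORDER) -> np.ndarray:
    return butterworth_filter(x, FilterSpec("lowpass", order, cutoff_hz), fs)


def locomotion_band(
    acc_ap: np.ndarray,
    fs: float,
    f_range: tuple[float, float] = (0.5, 3.0),
    wavelet: str = "morl",
) -> SpectralBand:
    """Locate the dominant locomotion band of anteroposterior acceleration.

    A continuous wavelet transform (Morlet mother wavelet; any standard
    analytic wavelet would serve, since only the band location is consumed)
    gives a time-frequency representation whose time-averaged power is
    scanned within ``f_range``.  The returned band is the contiguous region
    holding at least half the peak power.  This is a QC/reporting quantity:
    the fixed detection cutoffs are not derived from it at run time.
    """
    x = np.asarray(acc_ap, dtype=float)
    if x.size < 5 * fs:
        raise ValueError("need at least 5 s of signal for band estimation")
    x = x - x.mean()
    freqs = np.linspace(max(0.2, f_range[0] * 0.6), f_range[1] * 1.2, 120)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coeffs, actual = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    power = np.mean(np.abs(coeffs) ** 2, axis=1)
    in_range = (actual >= f_range[0]) & (actual <= f_range[1])
    if not np.any(in_range):
        raise ValueError("frequency grid does not cover the requested range")
    p = power[in_range]
    f = actual[in_range]
    i_peak = int(np.argmax(p))
    dominant = float(f[i_peak])
    clear = bool(p[i_peak] > 4.0 * np.median(p)) if p.size > 3 else True
    if not clear:
        warnings.warn("no clear locomotion peak in the spectrum", stacklevel=2)
    half = p >= 0.5 * p[i_peak]
    # contiguous half-power region around the peak
    lo = i_peak
    while lo > 0 and half[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < p.size - 1 and half[hi + 1]:
        hi += 1
    f_lo, f_hi = sorted((float(f[lo]), float(f[hi])))
    if f_lo == f_hi:  # single-bin peak
        f_lo, f_hi = f_lo - 0.05, f_hi + 0.05
    return SpectralBand(f_lo=f_lo, f_hi=f_hi, dominant_f=dominant, clear_peak=clear)


def fft_bin_highpass(
    x: np.ndarray,
    fs: float,
    cutoff_hz: float = YAW_CUTOFF,
    n_bins: int | None = None,
) -> np.ndarray:
    """High-pass a signal by zeroing low-frequency FFT bins.

    All bins with ``|f| < cutoff_hz`` — the DC bin included — are set to
    zero together with their conjugate partners, and the signal is rebuilt
    with the inverse FFT.  ``n_bins`` overrides the cutoff with a literal
    number of positive-frequency bins to zero (the record-length-dependent
    variant of the same operation).  The output is realigned to the input by
    maximizing circular cross-correlation; bin zeroing is itself zero-phase,
    so the applied shift is zero in practice and the step serves as a guard.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short for FFT filtering")
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff at or above Nyquist")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    if n_bins is not None:
        mask = np.arange(freqs.size) <= n_bins
    else:
        mask = freqs < cutoff_hz
    spec[mask] = 0.0
    y = np.fft.irfft(spec, n=x.size)
    # phase realignment by circular cross-correlation (frequency domain)
    xc = np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(y)), n=x.size)
    shift = int(np.argmax(xc))
    if shift:
        y = np.roll(y, shift)
    return y
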