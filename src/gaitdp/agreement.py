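"""Agreement statistics between estimated and reference step sequences.

Implements the validation toolbox used to compare per-step length estimates
against a reference stream: temporal pairing anchored on the first contact,
absolute and percent errors, median absolute error (MdAE) with its
interquartile range, Bland-Altman bias and limits of agreement, Pearson
correlation with ordinary least-squares regression, and the standard
normality / paired-difference tests (Shapiro-Wilk, Wilcoxon signed-rank).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSteps",
    "AgreementReport",
    "pair_steps",
    "absolute_error",
    "percent_error",
    "mdae_iqr",
    "bland_altman",
    "correlation_regression",
    "nonparametric_tests",
    "agreement_report",
    "group_report",
]

DEFAULT_PAIRING_TOL_S = 0.25
LOA_MULTIPLIER = 1.96


@dataclass
class PairedSteps:
    """Temporally matched estimated/reference step lengths (metres)."""

    est: np.ndarray
    ref: np.ndarray
    side: np.ndarray | None = None
    est_idx: np.ndarray | None = None  # positions of the pairs in the source streams
    ref_idx: np.ndarray | None = None
    subject_id: str = ""
    trial_id: str = ""
    n_unmatched_est: int = 0
    n_unmatched_ref: int = 0

    def __post_init__(self) -> None:
        self.est = np.asarray(self.est, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if self.est.shape != self.ref.shape:
            raise ValueError("est and ref must have equal length")
        if self.side is not None:
            self.side = np.asarray(self.side)
            if self.side.shape != self.est.shape:
                raise ValueError("side labels must match the pair count")

    @property
    def n(self) -> int:
        return self.est.size


@dataclass
class AgreementReport:
    """Summary statistics of one estimated-vs-reference comparison."""

    mdae: float
    iqr_lo: float
    iqr_hi: float
    pct_error_median: float
    bias: float
    bias_ci_lo: float
    bias_ci_hi: float
    loa_lo: float
    loa_hi: float
    r: float
    r2: float
    slope: float
    intercept: float
    n: int
    wilcoxon_stat: float = float("nan")
    wilcoxon_p: float = float("nan")
    shapiro_stat: float = float("nan")
    shapiro_p: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def pair_steps(
    est_times: np.ndarray,
    est_lengths: np.ndarray,
    ref_times: np.ndarray,
    ref_lengths: np.ndarray,
    tol: float = DEFAULT_PAIRING_TOL_S,
    est_sides: np.ndarray | None = None,
    align: str = "first_contact",
    **ids,
) -> PairedSteps:
    """Match estimated steps to reference steps by contact time.

    With ``align="first_contact"`` (two independently clocked systems) the
    first contact of each stream serves as the temporal anchor: estimated
    times are shifted by ``ref[0] - est[0]`` before matching.  With
    ``align="none"`` both streams are taken to share a clock.  Matching is
    greedy in time order to the nearest unused reference step within
    ``tol`` seconds; unmatched steps on either side are counted and
    excluded from all statistics.
    """
    est_times = np.asarray(est_times, dtype=float)
    ref_times = np.asarray(ref_times, dtype=float)
    est_lengths = np.asarray(est_lengths, dtype=float)
    ref_lengths = np.asarray(ref_lengths, dtype=float)
    if est_times.size == 0 or ref_times.size == 0:
        raise ValueError("cannot pair empty step sequences")
    if align not in ("first_contact", "none"):
        raise ValueError(f"unknown alignment mode {align!r}")
    offset = ref_times[0] - est_times[0] if align == "first_contact" else 0.0
    aligned = est_times + offset
    used = np.zeros(ref_times.size, dtype=bool)
    ie, ir, sides = [], [], []
    for i, t in enumerate(aligned):
        d = np.abs(ref_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            ie.append(i)
            ir.append(j)
    return PairedSteps(
        est=est_lengths[ie],
        ref=ref_lengths[ir],
        side=np.asarray(est_sides)[ie] if est_sides is not None else None,
        est_idx=np.asarray(ie, dtype=int),
        ref_idx=np.asarray(ir, dtype=int),
        n_unmatched_est=est_times.size - len(ie),
        n_unmatched_ref=ref_times.size - len(ir),
        **ids,
    )


def absolute_error(calculated: np.ndarray, estimated: np.ndarray) -> np.ndarray:
    """Signed error ``calculated - estimated``; its magnitude feeds the MdAE."""
    return np.asarray(calculated, dtype=float) - np.asarray(estimated, dtype=float)


def percent_error(calculated: np.ndarray, estimated: np.ndarray) -> np.ndarray:
    """Relative error ``100 * (estimated - calculated) / calculated``."""
    calculated = np.asarray(calculated, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if np.any(calculated == 0):
        raise ZeroDivisionError("reference step length of zero in percent error")
    return 100.0 * (estimated - calculated) / calculated


def mdae_iqr(errors: np.ndarray) -> tuple[float, float, float]:
    """Median and interquartile range of the absolute errors."""
    a = np.abs(np.asarray(errors, dtype=float))
    lo, hi = np.percentile(a, [25, 75])
    return float(np.median(a)), float(lo), float(hi)


def bland_altman(pairs: PairedSteps) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Bland-Altman bias, its 95% CI and the limits of agreement.

    Differences are ``est - ref``; the limits of agreement are
    ``bias +/- 1.96 * sd`` with the sample standard deviation (n - 1), and
    the CI of the bias uses the normal approximation.
    """
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs for Bland-Altman analysis")
    d = pairs.est - pairs.ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd)
    half = LOA_MULTIPLIER * sd / np.sqrt(pairs.n)
    return bias, (bias - half, bias + half), loa


def correlation_regression(pairs: PairedSteps) -> tuple[float, float, float, float]:
    """Pearson r, r^2, and OLS slope/intercept of est on ref."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs for correlation analysis")
    if np.ptp(pairs.ref) == 0:
        raise ValueError("zero variance in the reference lengths")
    res = stats.linregress(pairs.ref, pairs.est)
    r = float(res.rvalue)
    return r, r * r, float(res.slope), float(res.intercept)


def nonparametric_tests(pairs: PairedSteps) -> dict:
    """Shapiro-Wilk on the error distribution and Wilcoxon signed-rank.

    Returns a dict with ``shapiro_stat/p`` and ``wilcoxon_stat/p``; an
    all-zero difference vector makes the Wilcoxon test degenerate and is
    flagged with NaNs rather than raising.
    """
    if pairs.n < 8:
        raise ValueError("need at least 8 pairs for distributional tests")
    d = pairs.est - pairs.ref
    sw = stats.shapiro(d)
    out = {"shapiro_stat": float(sw.statistic), "shapiro_p": float(sw.pvalue)}
    if np.all(d == 0):
        warnings.warn("all differences are zero; Wilcoxon test degenerate", stacklevel=2)
        out.update(wilcoxon_stat=float("nan"), wilcoxon_p=float("nan"))
    else:
        w = stats.wilcoxon(pairs.est, pairs.ref)
        out.update(wilcoxon_stat=float(w.statistic), wilcoxon_p=float(w.pvalue))
    return out


def agreement_report(pairs: PairedSteps) -> AgreementReport:
    """Full agreement summary for one pooled set of paired steps."""
    err = absolute_error(pairs.ref, pairs.est)
    mdae, lo, hi = mdae_iqr(err)
    pct = float(np.median(percent_error(pairs.ref, pairs.est)))
    bias, ci, loa = bland_altman(pairs)
    r, r2, slope, intercept = correlation_regression(pairs)
    tests = nonparametric_tests(pairs) if pairs.n >= 8 else {}
    return AgreementReport(
        mdae=mdae,
        iqr_lo=lo,
        iqr_hi=hi,
        pct_error_median=pct,
        bias=bias,
        bias_ci_lo=ci[0],
        bias_ci_hi=ci[1],
        loa_lo=loa[0],
        loa_hi=loa[1],
        r=r,
        r2=r2,
        slope=slope,
        intercept=intercept,
        n=pairs.n,
        **tests,
    )


def group_report(per_subject: list[PairedSteps]) -> pd.DataFrame:
    """Per-subject and grand-median error table, by side.

    For each subject and side: MdAE, IQR bounds and median percent error of
    the paired steps.  The grand median row is the median of the per-subject
    medians (and the IQR of those medians), so it is invariant to subject
    ordering and robust to unequal step counts.
    """
    rows = []
    for p in per_subject:
        sides = np.unique(p.side) if p.side is not None else np.array(["all"])
        for s in sides:
            sel = slice(None) if p.side is None else (p.side == s)
            err = absolute_error(p.ref[sel], p.est[sel])
            if err.size == 0:
                continue
            mdae, lo, hi = mdae_iqr(err)
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "side": str(s),
                    "mdae": mdae,
                    "iqr_lo": lo,
                    "iqr_hi": hi,
                    "pct_error": float(np.median(percent_error(p.ref[sel], p.est[sel]))),
                    "n": int(err.size),
                }
            )
    df = pd.DataFrame(rows)
    grand = []
    for s, grp in df.groupby("side"):
        med = grp["mdae"].to_numpy()
        lo, hi = (np.percentile(med, [25, 75]) if med.size else (np.nan, np.nan))
        grand.append(
            {
                "subject_id": "Grand Median",
                "side": s,
                "mdae": float(np.median(med)),
                "iqr_lo": float(lo),
                "iqr_hi": float(hi),
                "pct_error": float(np.median(grp["pct_error"])),
                "n": int(grp["n"].sum()),
            }
        )
    return pd.concat([df, pd.DataFrame(grand)], ignore_index=True)
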