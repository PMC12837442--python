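"""End-to-end orchestration: configuration, the per-trial pipeline, and
cohort-level validation studies against synthetic ground truth."""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import yaml

from . import agreement, events, filters, integration, model, simulate
from .signals import ImuRecording, SubjectAnthropometrics

__all__ = ["PipelineConfig", "run_pipeline", "run_validation_study", "StudyResult"]

log = logging.getLogger("gaitdp")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters (defaults are the method's fixed values)."""

    hp_cutoff: float = filters.HP_CUTOFF  # Hz, detection high-pass
    lp_cutoff: float = filters.LP_CUTOFF  # Hz, detection low-pass
    hp_order: int = filters.HP_ORDER
    lp_order: int = filters.LP_ORDER
    yaw_cutoff: float = filters.YAW_CUTOFF  # Hz, FFT-bin high-pass for yaw
    yaw_bins: int | None = None  # literal bin count override for the yaw filter
    integration_lp_cutoff: float = filters.INTEGRATION_LP_CUTOFF  # Hz
    alpha: float = integration.DEFAULT_ALPHA  # forward/reverse blend weight
    reverse_anchor: str = "forward_end"  # forward_end | mean | zupt
    integration_anchor: str = "recording_start"  # recording_start | first_contact
    yaw_phase_stat: str = "delta"  # delta | end | mean
    pelvic_sign: float = model.DEFAULT_PELVIC_SIGN
    invert_vertical_gyro: bool = False
    pairing_tol: float = agreement.DEFAULT_PAIRING_TOL_S  # s
    trim_steps: int = 2  # first/last steps excluded from statistics
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.yaw_phase_stat not in ("delta", "end", "mean"):
            raise ValueError(f"unknown yaw_phase_stat {self.yaw_phase_stat!r}")
        if self.reverse_anchor not in ("forward_end", "mean", "zupt"):
            raise ValueError(f"unknown reverse_anchor {self.reverse_anchor!r}")
        if self.integration_anchor not in ("recording_start", "first_contact"):
            raise ValueError(f"unknown integration_anchor {self.integration_anchor!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _phase_yaw(yaw_f: np.ndarray, f0: float, f1: float, stat: str) -> tuple[float, float]:
    grid = np.arange(yaw_f.size)
    if stat == "delta":
        return float(np.interp(f0, grid, yaw_f)), float(np.interp(f1, grid, yaw_f))
    if stat == "end":
        return 0.0, float(np.interp(f1, grid, yaw_f))
    i0, i1 = int(round(f0)), int(round(f1))
    return 0.0, float(np.mean(yaw_f[i0 : i1 + 1]))


def run_pipeline(
    recording: ImuRecording,
    anthro: SubjectAnthropometrics,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[model.StepEstimate], dict]:
    """Execute preprocess -> detect -> segment -> integrate -> estimate.

    Returns the per-step estimates (initiation/termination steps flagged
    ``analyzed=False``) and a diagnostics dict recording event counts and
    dropped steps.  Per-step failures are isolated: a step whose velocity
    reconstruction is non-finite is dropped and logged, not fatal.
    """
    fs = recording.fs
    euler = recording.orientation()

    try:
        ic_idx, ic_pos = events.detect_initial_contacts(
            recording.acc_ap, fs, config.hp_cutoff, config.lp_cutoff,
            config.hp_order, config.lp_order, return_positions=True,
        )
    except ValueError as e:
        raise ValueError(f"ingest/detection: {e}") from e
    if ic_idx.size < 2:
        raise ValueError("ingest/detection: fewer than two initial contacts found")
    sides = events.assign_side(recording.gyro_vert, ic_idx, invert=config.invert_vertical_gyro)
    ms_idx, ms_pos = events.detect_midstance(euler.roll, fs, config.hp_cutoff, return_positions=True)
    ev = events.GaitEvents(ic_idx=ic_idx, ms_idx=ms_idx, side=sides, fs=fs, ic_pos=ic_pos, ms_pos=ms_pos)
    phases = events.segment_phases(ev, trim_steps=config.trim_steps)
    if not phases:
        raise ValueError("segmentation: no complete steps (IC-MS-IC) found")

    acc_f = integration.prefilter_acc(recording.acc_ap, fs, config.integration_lp_cutoff)
    # Trials are recorded from quiet standing; anchoring the zero initial
    # velocity at the recording start (instead of literally at the first
    # detected contact) realizes the same standstill assumption but is
    # insensitive to contact-detection jitter during gait initiation.
    anchor = 0 if config.integration_anchor == "recording_start" else int(ic_idx[0])
    pvs = integration.phase_velocity_pipeline(
        acc_f, phases, fs, alpha=config.alpha, anchor_idx=anchor
    )
    by_step: dict[int, dict[str, integration.PhaseVelocity]] = {}
    for pv in pvs:
        by_step.setdefault(pv.step_index, {})[pv.phase] = pv

    yaw_f = filters.fft_bin_highpass(euler.yaw, fs, config.yaw_cutoff, n_bins=config.yaw_bins)

    estimates: list[model.StepEstimate] = []
    n_failed = 0
    for k, ph in enumerate(phases):
        pv1, pv2 = by_step[k].get("E1"), by_step[k].get("E2")
        if pv1 is None or pv2 is None or not (pv1.ok and pv2.ok):
            n_failed += 1
            log.warning("step %d dropped: velocity reconstruction failed", k)
            continue
        y1 = _phase_yaw(yaw_f, ph.f_ic, ph.f_ms, config.yaw_phase_stat)
        y2 = _phase_yaw(yaw_f, ph.f_ms, ph.f_ic_next, config.yaw_phase_stat)
        e1 = model.PhaseKinematics(v_mean=pv1.v_mean, duration=ph.T_E1, yaw_start=y1[0], yaw_end=y1[1])
        e2 = model.PhaseKinematics(v_mean=pv2.v_mean, duration=ph.T_E2, yaw_start=y2[0], yaw_end=y2[1])
        est = model.step_length(
            e1, e2, anthro, ph.side,
            step_index=k,
            t_ic=float(recording.t[ph.i_ic]),
            pelvic_sign=config.pelvic_sign,
            analyzed=ph.analyzed,
        )
        estimates.append(est)
    diagnostics = {
        "n_ic": int(ic_idx.size),
        "n_ms": int(ms_idx.size),
        "n_steps": len(estimates),
        "n_analyzed": sum(e.analyzed for e in estimates),
        "n_failed": n_failed,
    }
    return estimates, diagnostics


@dataclass
class StudyResult:
    """Output of a synthetic cohort validation run."""

    pooled: agreement.AgreementReport
    per_group: dict[str, agreement.AgreementReport]
    per_subject: list[agreement.PairedSteps]
    table: object  # pandas DataFrame from agreement.group_report

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "per_group": {k: v.to_dict() for k, v in self.per_group.items()},
        }


def pair_trial(
    estimates: list[model.StepEstimate],
    truth: simulate.GroundTruth,
    tol: float = agreement.DEFAULT_PAIRING_TOL_S,
    analyzed_only: bool = True,
    **ids,
) -> agreement.PairedSteps:
    """Pair a trial's estimates against its generator ground truth.

    Truth and estimates share the recording clock, so matching is by
    absolute contact time (no first-contact re-alignment); trimmed
    estimates are removed from the matched set before statistics.
    """
    est_t = np.array([e.t_ic for e in estimates])
    est_l = np.array([e.L_total for e in estimates])
    est_sides = np.array([e.side for e in estimates])
    analyzed = np.array([e.analyzed for e in estimates])
    pairs = agreement.pair_steps(
        est_t, est_l, truth.ic_times[:-1], truth.step_lengths,
        tol=tol, est_sides=est_sides, align="none", **ids,
    )
    if analyzed_only:
        keep = analyzed[pairs.est_idx]
        pairs = agreement.PairedSteps(
            est=pairs.est[keep],
            ref=pairs.ref[keep],
            side=pairs.side[keep] if pairs.side is not None else None,
            est_idx=pairs.est_idx[keep],
            ref_idx=pairs.ref_idx[keep],
            subject_id=pairs.subject_id,
            trial_id=pairs.trial_id,
            n_unmatched_est=pairs.n_unmatched_est,
            n_unmatched_ref=pairs.n_unmatched_ref,
        )
    return pairs


def run_validation_study(
    n_subjects: int = 20,
    n_trials: int = 3,
    presets: list[str] | None = None,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    noise_acc: float | None = None,
    noise_yaw_deg: float | None = None,
    n_steps: int | None = None,
) -> StudyResult:
    """Simulate a cohort, run the pipeline, and report agreement vs truth.

    Each subject draws a preset (round-robin over ``presets``), individual
    anthropometrics, and trial-to-trial cadence/speed jitter.  Noise levels
    can be overridden uniformly (e.g. a zero-noise cohort).
    """
    rng = np.random.default_rng(seed)
    all_presets = simulate.scenario_presets()
    names = presets or list(all_presets)
    per_subject: list[agreement.PairedSteps] = []
    group_pairs: dict[str, list[agreement.PairedSteps]] = {}
    for s in range(n_subjects):
        name = names[s % len(names)]
        base = all_presets[name]
        lp = float(rng.normal(0.92, 0.04))
        anthro = SubjectAnthropometrics(lp_right=lp, lp_left=lp, rp=float(rng.normal(0.15, 0.01)))
        subj_pairs = []
        for tr in range(n_trials):
            sc = replace(
                base,
                anthro=anthro,
                seed=int(rng.integers(0, 2**31 - 1)),
                cadence=float(np.clip(base.cadence * rng.normal(1.0, 0.05), 1.0, 2.4)),
                mean_speed=float(base.mean_speed * rng.normal(1.0, 0.07)),
            )
            if noise_acc is not None:
                sc = replace(sc, noise_acc=noise_acc)
            if noise_yaw_deg is not None:
                sc = replace(sc, noise_yaw_deg=noise_yaw_deg)
            if n_steps is not None:
                sc = replace(sc, n_steps=n_steps)
            rec, truth = simulate.simulate(sc)
            est, _ = run_pipeline(rec, anthro, config)
            subj_pairs.append(
                pair_trial(est, truth, tol=config.pairing_tol,
                           subject_id=f"S{s:02d}", trial_id=f"T{tr}")
            )
        merged = agreement.PairedSteps(
            est=np.concatenate([p.est for p in subj_pairs]),
            ref=np.concatenate([p.ref for p in subj_pairs]),
            side=np.concatenate([p.side for p in subj_pairs]),
            subject_id=f"S{s:02d}",
        )
        per_subject.append(merged)
        group_pairs.setdefault(name, []).append(merged)

    def pool(ps: list[agreement.PairedSteps]) -> agreement.PairedSteps:
        return agreement.PairedSteps(
            est=np.concatenate([p.est for p in ps]),
            ref=np.concatenate([p.ref for p in ps]),
            side=np.concatenate([p.side for p in ps]),
        )

    pooled = agreement.agreement_report(pool(per_subject))
    per_group = {
        name: agreement.agreement_report(pool(ps))
        for name, ps in group_pairs.items()
        if sum(p.n for p in ps) >= 8
    }
    table = agreement.group_report(per_subject)
    return StudyResult(pooled=pooled, per_group=per_group, per_subject=per_subject, table=table)
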