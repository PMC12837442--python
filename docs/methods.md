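# Methods

## The model

`gaitdp` estimates per-step length from a single inertial sensor worn over
the sacrum, using an inverted-double-pendulum view of walking: each leg acts
as an inverted pendulum during its stance phase, and the pelvis couples the
two pendulums while rotating in the transverse plane. A step — from the
initial contact (IC) of one foot to the IC of the other — is split at
mid-stance (MS) into a braking phase E1 (the body decelerates as the center
of mass approaches the support ankle) and a propulsion phase E2.

Per phase, the step length decomposes into

- a **pendular** term. Inverted-pendulum kinematics link forward speed,
  cadence and length through `V = C·L`. Normalizing by the Froude number
  `Fr = V²/(g·Lp)` (with `Lp` the stance leg's
  greater-trochanter-to-sole length) makes the relation comparable across
  body sizes; solving for the length gives
  `L_pendular = sqrt(Fr·g·Lp)/C`, algebraically equal to `V/C`. The phase
  cadence is the reciprocal of the phase duration, `C = 1/T`, so the
  pendular term is exactly the kinematic phase displacement `V·T`. `V` is
  the phase's integrated average anteroposterior velocity and `Fr` is
  computed per phase, so braking and propulsion may differ — the feature
  that lets the model represent asymmetric gait.
- a **pelvic** term. Transverse pelvic rotation advances the swinging hip by
  `L_pelvic = rp·tan(Δyaw)`, where `rp` is the pelvic radius (mid-sacrum to
  iliac crest) and `Δyaw` the net rotation of the filtered pelvic yaw over
  the phase. The full tangent (not the small-angle form) keeps the
  projection valid at the larger compensatory angles of impaired gait;
  physiologic pelvic rotation stays within roughly ±20°, far from the
  tangent singularities at ±90°. The term enters with a fixed sign
  convention (subtracted, matching the model's printed form); both the
  generator's ground truth and the estimator share the convention, and a
  `pelvic_sign` configuration flips it for sensors with the opposite yaw
  polarity. A consequence worth knowing: with stride-periodic yaw the
  pelvic term alternates sign between left and right steps, so even
  otherwise symmetric gait shows a small side difference (≈ 2·rp·tan(yaw
  amplitude)).

The total per step is the sum of both terms over both phases. Leg length is
taken from the stance side.

## Signal processing

1. **Event detection** works on the unrotated body-frame signals.
   - Initial contacts: the anteroposterior acceleration is reduced to its
     fundamental locomotion wave (zero-phase Butterworth high-pass 0.5 Hz
     order 4, then low-pass 1.8 Hz order 4); contact appears as the wave's
     deceleration valley. Candidate valleys (derivative zero-crossings that
     follow a peak) pass an adaptive depth threshold — 0.22 × the median
     candidate depth in a sliding 5 s window, floored at 0.15 × the
     trial-wide upper-quartile depth so quiet standing produces no events —
     and are then localized within ±4 samples on a broader band
     (0.5–9 Hz), because narrow-band filtering skews valley positions when
     left and right step periods differ. A parabolic three-point fit gives
     sub-sample positions; integer indices are quantized with the trial's
     median sub-sample offset removed first, which stops a common
     half-sample skew from flipping neighbouring events by one sample. A
     0.25 s refractory period enforces physiologic step spacing.
   - Mid-stances: the frontal-plane roll is band-passed the same way
     (high-pass to centre it, low-pass against sensor noise); both maxima
     and minima of the trace are mid-stance events, refined identically.
   - Limb assignment: the vertical angular velocity averaged over the four
     samples after a contact; positive (pelvis swinging right) means left
     stance, negative means right. Zero-mean cases are resolved by
     alternation with their neighbours; a config flag accommodates
     upside-down mounting.
   - Steps are consecutive contacts bracketing exactly one mid-stance;
     others are dropped with a warning. The first and last two steps are
     flagged and excluded from statistics (gait initiation/termination).
2. **Pelvic yaw** comes from the sensor's orientation quaternions,
   converted to intrinsic Z-Y-X Euler angles (yaw about the gravity-aligned
   vertical axis) and unwrapped. Offset and slow drift are removed by an
   FFT-bin high-pass: all bins below 0.25 Hz (DC included) are zeroed and
   the signal rebuilt by inverse FFT; a literal bin-count override
   (`yaw_bins`) reproduces the record-length-dependent variant. Bin zeroing
   is zero-phase; a cross-correlation/circular-shift realignment guards the
   output anyway.
3. **Velocity reconstruction** (drift-corrected forward/reverse
   integration). The anteroposterior acceleration is low-pass filtered
   (zero-phase Butterworth, order 2, 3.5 Hz) and integrated with the
   trapezoidal rule. Initial conditions chain across phases: the first
   braking phase starts at zero velocity — the method assumes trials are
   recorded from quiet standing — each propulsion phase starts at its
   braking phase's final velocity, and each subsequent braking phase at the
   final velocity of the preceding one (implemented as one continuous
   integral sliced per phase, which realizes the chaining exactly even
   across dropped steps). Reverse integration is anchored at the forward
   end value, blended with weight α = 0.5, and a linear ramp removes the
   endpoint error `Ev`, estimated as the gap between the blended endpoint
   and the phase mean (a zero endpoint cannot be assumed for a
   lumbar-mounted sensor). Phase means, durations and endpoints are
   evaluated on the sub-sample event windows; the endpoint velocity uses a
   ±30 ms symmetric average so `Ev` is insensitive to boundary
   quantization. The zero-velocity anchor is placed at the recording start
   by default (`integration_anchor="recording_start"`): recordings begin at
   a standstill, and anchoring there realizes the same assumption as the
   literal "zero at the first contact" rule while being immune to
   contact-detection jitter during gait initiation (the literal rule is
   available as `first_contact`).

## The synthetic-data generator

`gaitdp.simulate` builds a forward center-of-mass velocity trajectory from
a kinematic gait plan and differentiates it analytically, so the emitted
acceleration is exactly consistent with the trajectory and the ground truth
is the trajectory's own displacement integral plus the pelvic projection
(same sign convention as the model). What it emulates:

- a step-frequency velocity oscillation (default amplitude 12% of the mean
  speed) whose deceleration extreme falls at each contact — the source of
  the detector's valley;
- a contact-locked impact transient: a velocity dip of 0.04 m/s
  (`impact_sharpness` scales it), Gaussian with σ = 10 ms, centered 15 ms
  after the contact (the loading response peaks just after touch-down);
- stride-periodic pelvic yaw, phased so the vertical angular velocity just
  after a left-stance contact is positive, and stride-periodic roll with an
  extremum at every mid-stance;
- left/right asymmetry: `asym_len` modulates speed over the stride phase so
  the left/right step-length ratio equals `1 + asym_len` exactly;
  `asym_time` makes step durations differ by side (phase kept C¹-smooth
  through the contacts);
- white Gaussian sensor noise on accelerations (default 0.15 m/s²), angular
  velocity (0.02 rad/s) and orientation angles (0.5°) — defaults are the
  moderate-noise study condition;
- gait initiation and termination (default regime): quiet standing, an
  anticipatory weight-shift sway that brakes to an exact zero-velocity
  plateau (±50 ms) at the first contact, smooth quintic speed ramps over
  about two steps, and a mirrored slow-down. This is the regime the
  integration anchor assumes. `initiation=False` gives steady-state walking
  across the whole record (for isolated event-detection validation), with
  record edges placed at zero-crossings of the gait wave so the zero-phase
  filters' reflective padding introduces no boundary transient.

Five presets (`healthy_adult`, `older_adult`, `asymmetric_mild`,
`asymmetric_severe`, `shuffling`) span the targeted phenotypes; their
amplitudes are plausible synthetic values, not measured cohort statistics.
The severe-asymmetry preset uses a larger within-step ripple (impaired gait
shows stronger per-step speed fluctuation), and the shuffling preset's weak
ripple and impact make it the intended detector stress case.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: gravity leakage from imperfect sensor-frame
alignment, orientation-fusion drift and magnetic disturbance, soft-tissue
artifact, turning or non-straight walking, and genuinely pathological event
morphology (absent stance-to-swing transitions). Ground truth is defined by
the same geometric decomposition the model assumes, so closed-loop errors
measure pipeline fidelity, not model-vs-reality bias.

## Numerical choices

- All Butterworth filters are applied forward-backward (zero phase) with up
  to 2 s of reflective padding; stated orders are single-pass design
  orders.
- Trapezoidal integration throughout; ground-truth displacement uses the
  same rule, so integration-rule error cancels in the closed loop.
- Event refinement is sub-sample (parabolic vertex); whole-sample
  quantization otherwise dominates the noise-free error budget (1 sample ≈
  13 mm at 1.3 m/s).
- Degenerate inputs: flat signals yield empty event lists with warnings;
  steps whose velocity reconstruction is non-finite are dropped and logged,
  not fatal; an all-zero difference vector makes the Wilcoxon test
  degenerate and is flagged with NaNs.
- Pairing against a reference stream matches greedily by contact time
  within 0.25 s; cross-system comparisons align on the first contact,
  same-clock comparisons (generator truth) use absolute times.
- Agreement statistics: limits of agreement at ±1.96 sample standard
  deviations; bias CI by normal approximation; grand medians are medians of
  per-subject medians (invariant to subject order).

## Known limitations

- The per-phase ramp correction removes within-phase drift only; error
  accumulated through the chained initial conditions (e.g. a miscalibrated
  accelerometer bias) survives it. On drifting input the correction reduces
  but does not eliminate the velocity error.
- The method requires trials recorded from a standstill; for recordings
  that begin mid-walk the velocity scale is unobservable from the
  anteroposterior channel alone (only the literal first-contact anchor can
  be used, and it will be biased by whatever speed the subject already
  has).
- In strongly time-asymmetric gait the soft side's contact valleys weaken;
  below the depth threshold those steps are dropped rather than
  mis-measured.
- Validation problem sizes: cohorts of 20 subjects × 3 trials of 16 steps
  each, and 20-seed ladders per condition, chosen as the smallest sizes at
  which the pooled statistics are stable.
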