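# Methods

This note documents the models, conventions and numerical choices behind
gaitkit, and what its synthetic tests do and do not demonstrate about real
recordings.

## Coordinate frame and conventions

The lab frame has X pointing to the subject's right, Y up, and Z backward
(the subject walks in −Z); the origin lies on the treadmill surface and is
shared by the cameras and the force-plate system.  Sagittal-plane analysis
drops X and represents a point as the complex number `z + i y`; a positive
rotation about +X (right-hand rule) multiplies that number by `exp(-i a)`.

Joint angles use the aligned-configuration zero: hip, knee and ankle angles
all vanish when the shoulder→hip, hip→knee, knee→ankle and heel→toe vectors
are parallel.  Each angle is the signed rotation about +X carrying the
proximal vector onto the distal one.  Consequences worth knowing: hip
flexion (thigh forward) is positive, knee flexion is negative, and a
straight-standing, foot-flat posture reads hip = knee = 0, ankle = +π/2.

Force plate 1 is under the left belt, plate 2 under the right.  Centers of
pressure relate to plate moments through `CoP_x = −M_z/F_y`,
`CoP_z = M_x/F_y`, `CoP_y = 0` on the belt surface; samples with
|F_y| < 20 N have no defined CoP.  The sagittal moment contribution of the
fore-aft force at the surface plane is absorbed into this convention; the
synthetic generator emits moments under the same convention, so
compensation and CoP re-derivation round-trip exactly.  g = 9.81 m/s².

## File formats and cleaning

`mocap-xxx.txt` sample times are derived from the frame counter, not the
time stamps: the frame rate is the reciprocal of the **median** of
ΔTimeStamp/ΔFrameNumber and times are laid out exactly linearly in frame
number from the first stamp.  The median makes the rate immune to sparse
buffering delays; if more than half of the inter-frame intervals were
disturbed the estimate would degrade, but that is not how acquisition
buffering behaves.

Missing markers are flagged per the recording-software dialect.  New
dialect (>= 3.16.2rc4): a frame is missing iff all three coordinates are
±0.0.  Old dialect: the software repeats the last seen value, so a marker
is flagged when all three coordinates are exactly equal to the previous
frame's for a run of at least 3 frames (from the run's second frame
onward).  Two identical frames are treated as a genuinely stationary
marker — at six printed decimals a 3-frame, three-axis exact repeat of a
marker on a moving body is not plausible.  Gaps are filled by linear,
cubic-spline or hold interpolation; unmasked samples are never touched, and
leading/trailing gaps take the nearest valid value.

The two streams are merged at the slower of the two stream rates (in
practice the ~100 Hz camera rate) over their overlapping span; record
columns are linearly interpolated onto the uniform mocap-derived grid.
Event segmentation returns rows from the named event to the next, with
times re-based to zero.  Force re-zeroing over the "Force Plate Zeroing"
window is available but off by default, since the hardware zeroes at each
trial start.

Body mass is measured as the mean of (FP1.ForY + FP2.ForY)/g over a window
after the "Calibration Pose" event.  The window defaults to 1.0 s — long
enough to average sensor noise, short enough to stay inside the pose.

Belt-inertia load compensation fits, per load channel, an ordinary
least-squares line from belt acceleration to load on an unloaded
(no-subject) trial, and subtracts the prediction on loaded trials.  Belt
acceleration is a central difference of the measured belt speed after a
zero-phase 2nd-order 6 Hz low-pass (matching the kinematics filter).  A fit
on a zero-acceleration-variance trial is refused unless the load channel is
constant, in which case the model reduces to a pure intercept.

## Perturbation signals

Longitudinal: white-noise acceleration at 100 Hz → saturation at
±15 m/s² → integration → causal 2nd-order Butterworth high-pass → add the
nominal speed → clip to [0, 3.6] m/s.  Causal (forward-only) filtering is
used here deliberately — the signal must be generatable in real time.  The
high-pass cutoff is fixed at 0.1 Hz: low enough to preserve the sub-4 Hz
band that actually perturbs the subject, high enough to remove
random-walk drift.  With the cutoff fixed, calibration is one-dimensional:
the white-noise SD is bisected until the mean sample SD over >= 10 seed
realizations is within tolerance of the target.  The shipped values

| nominal speed | target SD | calibrated noise SD |
|---|---|---|
| 0.8 m/s | 0.06 m/s | 0.800781 m/s² |
| 1.2 m/s | 0.12 m/s | 1.601562 m/s² |
| 1.6 m/s | 0.21 m/s | 2.796875 m/s² |

were produced by that procedure (50 seeds, 0.2% tolerance).  The signal SD
is nearly linear in the noise SD because the clamps almost never engage at
these levels.  Sample SDs of individual realizations scatter a few percent
(the variance concentrates near the 0.1 Hz corner, so a 480 s signal holds
only a few hundred effective samples); averages over 10 seeds stay within
about 2% of the target.

Lateral: the same chain with a second integration (displacement) and
saturation at the ±5 cm hardware travel; the default noise SD (0.1 m/s²)
keeps the displacement SD near 1.2 cm so the limiter engages rarely.

Spectral densities use Welch averaging with 20 s Hamming windows and 50%
overlap, normalized so the integral over frequency approximates the signal
variance.

## Gait cycles and stride statistics

Heel strikes/toe offs are upward/downward threshold crossings of the
vertical GRF at 20 N, with the crossing instant linearly interpolated
between the bracketing samples (at 100 Hz, nearest-sample timing would be
10 ms coarse) and a 0.2 s refractory period against chatter (the shortest
plausible stance or swing far exceeds it).  Cycles are the intervals
between consecutive heel strikes of one side, linearly resampled onto a
101-point 0–100% grid; cycles whose duration deviates more than 50% from
the trial median are dropped and reported.

Stride statistics per cycle: average belt speed (mean of the splitting
side's belt speed); stride frequency (1/duration); stride length (integral
of belt speed over the cycle plus the change of the heel's
forward-positive position from cycle start to end — a heel landing short
of its start shortens the stride); stride width (absolute lateral distance
between the two heel markers, each sampled at its own side's heel strike
within the cycle).  Treadmill stride length and width have no universal
definition; these are documented choices, so absolute magnitudes from
other definitions will differ.  Scalar summaries use Tukey-hinge
(midpoint) quartiles — stated because quartile conventions differ across
software.

## 2D inverse dynamics

Marker kinematics are filtered with a zero-phase (forward-backward)
2nd-order Butterworth low-pass at 6 Hz — appropriate for offline analysis,
and deliberately different from any causal real-time variant — then
differentiated twice by central differences (one-sided at the ends).
Segment angular positions come from the orientation of the
proximal→distal vector; COM positions sit at a fixed fraction of that
vector.

Each leg is a three-segment chain (foot, shank, thigh) with Winter-style
proportional inertia: mass fractions 0.0145/0.0465/0.100 of body mass, COM
at 0.50/0.433/0.433 of segment length from the proximal end, radius of
gyration 0.475/0.302/0.323 of length.  The table is config-swappable; the
classic normative values are defaults, not measurements.  The Newton–Euler
recursion runs from the foot up: ankle loads from foot equilibrium with
the GRF applied at the CoP, knee from the shank, hip from the thigh;
torques are net internal joint torques about +X.

Samples whose vertical GRF is below 20 N are treated as swing and the
external load is set exactly to zero, rather than feeding the sub-threshold
plate signal through — otherwise plate noise leaks into swing-phase
torques.  This gating is a deliberate choice of this implementation.

## The synthetic walker

The generator prescribes kinematics; it does not integrate equations of
motion.  Joint angles are two-harmonic Fourier series in stride phase
(left leg shifted half a stride), the pelvis bobs and sways with small
prescribed amplitudes over a hip point that stays above the treadmill, and
markers follow by planar forward kinematics.  Vertical GRFs are double-hump
profiles, sin(πu) + 0.3 sin(3πu) on stance-normalized time u with a 60%
duty factor, scaled so each leg's stance impulse equals half of body
weight times stride duration — hence the stride-averaged total vertical
force equals body weight by construction, and the calibration-pose window
carries exactly mg split across the plates.  Fore-aft GRFs are biphasic
sines integrating to zero; the CoP progresses heel→toe through stance.

The stride schedule couples gait to the belt: at each heel strike the
stride length follows the affine law L(v) = 0.72 + 0.44 v (1.25 m at
1.2 m/s, stride frequency 0.96 Hz) evaluated at the current belt speed,
and duration is L/v; stride width responds as w(v) = 0.12 + 0.08 (v − v̄).
Under a constant belt every stride is identical; under belt-speed
perturbations the stride statistics disperse — which is exactly the
qualitative contrast the perturbed/unperturbed comparison tests assert.
Quiet-stance phases carry a sub-millimeter postural sway so that standing
markers are never bit-identical across frames (a bit-constant marker would
be indistinguishable from an old-dialect dropout).

Time stamps carry sparse positive buffering delays (5% of frames, up to
3 ms) over an exact 100 Hz frame grid, matching how the acquisition
software time-stamps received frames and leaving the median-slope rate
estimate exact.

Ground-truth torques are evaluated through the **same** Newton–Euler
routine the pipeline uses, but with analytic derivatives of the prescribed
kinematics; the oracle therefore shares the mechanical equations while
bypassing the filtering/differentiation path it validates.  Corruption
(Gaussian marker/force noise, missing-marker injection in either dialect)
is applied after truth extraction, with a log of injected frames.

### Fidelity boundary

The walker satisfies stride-averaged impulse balance, not instantaneous
whole-body dynamics: the prescribed GRFs are not the forces a physical
body with these kinematics would produce frame by frame.  Soft-tissue
artifact, marker swaps, treadmill vibration modes, belt-speed measurement
lag and 3D (frontal/transverse) motion are all absent.  Passing recovery
tests therefore demonstrates the correctness of the numerical pipeline —
parsing, cleaning, event detection, differentiation, filtering and the
recursion — not the biomechanical fidelity of any model to real gait.

## Problem sizes in tests and the acceptance script

Synthetic trials in the test suite and acceptance script use walking
phases of 40–80 s (roughly 40–80 gait cycles) at the full 100 Hz rate, and
perturbation statistics use the full 480 s signal duration; these sizes
give stable statistics while keeping runs quick.  End-to-end error
measurements trim 2 s at the walking-segment boundaries, where the
standing↔walking transition of the prescribed kinematics (a modeling
discontinuity, not a pipeline property) dominates the filtered estimates.

## Known limitations

* Only a static-platform linear belt-acceleration compensation model is
  provided; full inertial compensation for lateral/pitch platform motion
  (accelerometer-based) is out of scope.
* Gait events come from the GRFs only; there is no kinematic fallback for
  trials with corrupt force data.
* The exact noise variances and high-pass cutoffs used to produce the
  original treadmill control signals are unpublished; the shipped
  calibration reproduces the target signal SDs, not the original
  waveforms.
* Stride length/width definitions (and hence their absolute magnitudes)
  are this package's documented choices.
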