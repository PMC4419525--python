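# gaitkit

A toolkit for perturbed treadmill gait experiments: it reads the
three-file trial format produced by a D-Flow/Cortex motion-capture
laboratory, cleans and merges the raw streams, detects gait events from the
ground reaction forces, computes sagittal-plane joint angles, angular rates
and torques by 2D link-segment inverse dynamics, and synthesizes the
pseudo-random belt-speed perturbation signals used to perturb the subjects.
A fully ground-truthed synthetic planar-walker generator makes the entire
pipeline testable at desk scale, without any recorded data.

It is aimed at researchers analyzing instrumented-treadmill walking data —
in particular trials where subjects walk on a dual-belt treadmill while the
belt speed is randomly perturbed around a nominal speed (0.8, 1.2 or
1.6 m/s) — and at anyone who needs compatible perturbation signals or
synthetic gait trials for method development.

## The data format

Each trial lives in a directory `T<nnn>/` with three files:

* `mocap-<nnn>.txt` — tab-separated stream at ~100 Hz: `TimeStamp`,
  `FrameNumber`, 47-marker coordinates (`<LABEL>.Pos[XYZ]`, meters),
  force-plate loads (`FP{1,2}.For[XYZ]` N, `.Mom[XYZ]` N m, `.Cop[XYZ]` m;
  plate 1 under the left foot), and analog channels (`Channel<k>.Anlg`).
  All values are fixed-point with six decimals.  Missing markers appear as
  signed-zero triplets (recording software >= 3.16.2rc4) or as frozen
  last-seen values (older versions).
* `record-<nnn>.txt` — `Time`, `RightBeltSpeed`, `LeftBeltSpeed`, with
  `#`-commented lines marking the protocol events A–F (force-plate zeroing,
  calibration pose, first normal walking, longitudinal perturbation, second
  normal walking, unloaded end).
* `meta-<nnn>.yml` — YAML metadata with `study`, `subject` and `trial`
  sections (marker/channel relabeling maps, event names, file roles, the
  recording-software version, nominal speed, subject anthropometry).

## The methods at the core

* **Belt-speed perturbations**: Gaussian white-noise acceleration a(t) at
  100 Hz, saturated at |a| <= 15 m/s², integrated to speed, high-pass
  filtered (2nd-order Butterworth, causal) to remove drift, shifted to the
  nominal speed v̄ and clipped to [0, 3.6] m/s.  The noise SD is calibrated
  by bisection so the signal SD matches the study values
  (0.06/0.12/0.21 m/s at 0.8/1.2/1.6 m/s).
* **Gait events**: heel strike and toe off as upward/downward 20 N
  crossings of each plate's vertical GRF, sub-sample interpolated, with a
  0.2 s refractory debounce.
* **Inverse dynamics**: markers are projected on the sagittal (Z,Y) plane;
  joint angles use the aligned-configuration convention (hip, knee, ankle
  all zero when trunk, thigh, shank and heel→toe line up); kinematics are
  zero-phase low-pass filtered at 6 Hz and differentiated; a planar
  Newton–Euler recursion from the foot upward (GRF applied at the center of
  pressure, Winter-style segment inertia fractions) yields the net ankle,
  knee and hip torques about the lab +X axis.
* **Stride statistics**: cycles split at one side's heel strikes and
  resampled to 0–100%; per cycle the average belt speed, stride frequency
  (1/duration), stride length (belt-speed integral plus heel fore-aft
  drift) and stride width (lateral heel separation at the respective heel
  strikes), summarized with Tukey-hinge quartiles.

## Worked example

Generate a synthetic unperturbed trial at 1.2 m/s, then split the first
normal-walking minute into gait cycles:

```sh
$ gaitkit synth demo --walk 20 --unperturbed --seed 1
$ gaitkit cycles demo/T020 --event "First Normal Walking"
{
 "n_cycles": 19,
 "stride_stats_five_number": {
  "Average Belt Speed":  {"median": 1.2},
  "Stride Frequency":    {"median": 0.9615},
  "Stride Length":       {"median": 1.2481},
  "Stride Width":        {"median": 0.12}
 }
}
```

Nineteen cycles at a constant 1.2 m/s belt: stride frequency 0.96 Hz and
stride length 1.25 m are exactly the generator's preferred stride law at
that speed (frequency x length = belt speed), and the 12 cm stride width is
the nominal heel separation.  A perturbation signal file for the treadmill
controller:

```sh
$ gaitkit perturb --speed 1.2 --duration 480 --seed 1 --out sig.csv
{"output": "sig.csv", "mean": 1.1995, "sd": 0.1162, "noise_sd": 1.601562}
```

The 480 s signal averages the nominal 1.2 m/s and its sample SD sits near
the calibrated 0.12 m/s target.  The study participant summary from the
packaged subject table:

```sh
$ gaitkit summarize
{"n": 15, "gender_counts": {"male": 11, "female": 4},
 "mean_age": 24, "sd_age": 4, "mean_height": 1.75, "sd_height": 0.09, ...}
```

The Python API mirrors the commands (`gaitkit.trial_io`,
`gaitkit.cleaning`, `gaitkit.gait_cycles`, `gaitkit.dynamics2d`,
`gaitkit.perturbation`, `gaitkit.synthetic`, `gaitkit.report`); see
`docs/methods.md` for the model details and design choices.

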