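"""Ground-truthed synthetic treadmill trials.

Generates complete trial directories (mocap/record/meta files) emulating the
study protocol with a kinematically prescribed planar walker, so that
parsing, cleaning, event detection, cycle statistics and inverse dynamics
are all testable at desk scale without any recorded data.

The walker is not forward-dynamically simulated: joint angles are smooth
low-order Fourier series in stride phase (the left leg shifted by half a
stride), marker positions follow by planar forward kinematics under a pelvis
that stays over the treadmill, and vertical ground reaction forces are
double-hump profiles scaled so each leg's stance impulse equals half of body
weight times stride duration (so the stride-averaged total equals body
weight).  Belt-speed fluctuations modulate the stride schedule: each
stride's length, duration and width respond to the belt speed at its heel
strike, which is what makes perturbed trials disperse their stride
statistics.

The ground truth (event, heel-strike and toe-off times; joint angles, rates
and torques; body mass) is evaluated with analytic derivatives through the
same Newton-Euler equations the measurement pipeline uses, so the truth
shares the model but not the numerical differentiation/filtering path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gaitkit import trial_io
from gaitkit.cleaning import GRAVITY
from gaitkit.dynamics2d import SegmentParams, default_segment_params, newton_euler_leg
from gaitkit.perturbation import PerturbationParams, generate_belt_signal
from gaitkit.trial_io import Event, EventTimeline, MetaData, TrialBundle

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_gait",
    "corrupt",
    "emit",
    "DEFAULT_PHASES",
]

#: Protocol phase durations in seconds: force-plate zeroing, calibration
#: pose, first normal walking (1 min), longitudinal perturbation (8 min),
#: second normal walking (1 min), unloaded end.
DEFAULT_PHASES = {
    "zeroing": 10.0,
    "calibration": 10.0,
    "first_normal": 60.0,
    "perturbation": 480.0,
    "second_normal": 60.0,
    "unloaded": 10.0,
}

PHASE_EVENTS = ["A", "B", "C", "D", "E", "F"]

DUTY_FACTOR = 0.6          # stance fraction of the stride
GRF_SHAPE_HARMONIC = 0.3   # relative third-harmonic weight of the vertical hump
FORE_AFT_AMPLITUDE = 0.15  # peak fore-aft GRF as a fraction of body weight
HEEL_DROP = 0.04           # m, heel marker offset along the shank past the ankle


@dataclass
class SynthConfig:
    """Study conditions for one synthetic trial."""

    mass: float = 74.0               # kg
    height: float = 1.75             # m
    nominal_speed: float = 1.2       # m/s
    phases: dict = field(default_factory=lambda: dict(DEFAULT_PHASES))
    perturbation: PerturbationParams | None = None
    missing_rate: float = 0.0        # fraction of marker frames corrupted
    marker_noise: float = 0.0        # m, Gaussian SD
    force_noise: float = 0.0         # N, Gaussian SD
    dflow_version: str = "3.16.2rc4"
    rate: float = 100.0              # Hz
    seed: int = 0
    trial_id: int = 20
    subject_id: int = 8

    def validate(self) -> None:
        if any(v < 0 for v in self.phases.values()):
            raise ValueError("phase durations must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def stride_length_law(speed: float | np.ndarray) -> float | np.ndarray:
    """Preferred stride length (m) as an affine function of belt speed."""
    return 0.72 + 0.44 * np.asarray(speed, dtype=float)


def stride_width_law(speed, nominal: float) -> float | np.ndarray:
    """Lateral heel separation (m); widens with belt-speed deviations."""
    return 0.12 + 0.08 * (np.asarray(speed, dtype=float) - nominal)


class _Fourier:
    """Low-order Fourier series in stride phase with analytic derivatives."""

    def __init__(self, c0, cos_coeffs=(), sin_coeffs=()):
        self.c0 = c0
        self.a = np.asarray(cos_coeffs, dtype=float)
        self.b = np.asarray(sin_coeffs, dtype=float)
        self.k = 2.0 * np.pi * np.arange(1, max(len(self.a), len(self.b)) + 1)

    def _terms(self, phi, order):
        phi = np.asarray(phi, dtype=float)
        arg = np.multiply.outer(self.k, phi)
        a = np.zeros(len(self.k))
        a[: len(self.a)] = self.a
        b = np.zeros(len(self.k))
        b[: len(self.b)] = self.b
        if order == 0:
            return self.c0 + np.tensordot(a, np.cos(arg), 1) + np.tensordot(b, np.sin(arg), 1)
        if order == 1:
            return np.tensordot(-a * self.k, np.sin(arg), 1) + np.tensordot(b * self.k, np.cos(arg), 1)
        return np.tensordot(-a * self.k**2, np.cos(arg), 1) + np.tensordot(-b * self.k**2, np.sin(arg), 1)

    def val(self, phi):
        return self._terms(phi, 0)

    def d1(self, phi):
        return self._terms(phi, 1)

    def d2(self, phi):
        return self._terms(phi, 2)


#: Joint angle trajectories over one stride (phase 0 = heel strike).
#: Conventions: hip flexion (thigh forward) positive, knee flexion negative,
#: ankle about +pi/2 at foot-flat.
GAIT_ANGLES = {
    "hip": _Fourier(0.0, [0.30], [0.10]),
    "knee": _Fourier(-0.45, [0.15, 0.20], [0.25, -0.10]),
    "ankle": _Fourier(np.pi / 2.0, [-0.10, 0.05], [0.15, 0.05]),
}

#: Pelvis excursions over one stride (m).
HIP_SWAY_Z = _Fourier(0.0, [], [0.02])
HIP_BOB_Y = _Fourier(0.0, [0.0, 0.015])

#: Quiet-stance postural sway (m) so standing markers are never bit-constant.
STANDING_SWAY = ((5.0e-4, 0.30), (3.0e-4, 0.23))  # (amplitude, frequency Hz) z, y


@dataclass
class GroundTruth:
    """Exact generation-time quantities matching the emitted trial."""

    mass: float
    events: dict                      # event name -> time (s)
    heel_strikes: dict                # side -> np.ndarray (s)
    toe_offs: dict
    joint_traces: pd.DataFrame        # "<Side> <Joint> Angle|Rate|Torque"
    segment_params: SegmentParams
    stride_schedule: pd.DataFrame     # per right stride: start, duration, speed, width
    config: SynthConfig

    def save(self, path: str | os.PathLike) -> None:
        self.joint_traces.to_hdf(path, key="truth_traces", mode="w")
        pd.Series(self.events).to_hdf(path, key="truth_events", mode="a")
        for side in ("left", "right"):
            pd.Series(self.heel_strikes[side]).to_hdf(path, key=f"truth_hs_{side}", mode="a")
            pd.Series(self.toe_offs[side]).to_hdf(path, key=f"truth_to_{side}", mode="a")
        pd.Series({"mass": self.mass}).to_hdf(path, key="truth_scalars", mode="a")
        self.stride_schedule.to_hdf(path, key="truth_strides", mode="a")


def _segment_geometry(height: float) -> dict:
    return {
        "trunk": 0.288 * height,   # greater trochanter to acromion
        "thigh": 0.245 * height,
        "shank": 0.246 * height,
        "foot": 0.152 * height,    # heel to toe
        "hip_height": 0.530 * height,
    }


def _grf_shape(u: np.ndarray) -> np.ndarray:
    """Double-hump vertical GRF profile on stance-normalized time u in [0,1]."""
    return np.sin(np.pi * u) + GRF_SHAPE_HARMONIC * np.sin(3.0 * np.pi * u)


#: Integral of the double-hump shape over u in [0, 1].
_GRF_SHAPE_INTEGRAL = 2.0 / np.pi + GRF_SHAPE_HARMONIC * 2.0 / (3.0 * np.pi)


def simulate_gait(config: SynthConfig) -> tuple[TrialBundle, GroundTruth]:
    """Simulate a full protocol trial and its exact ground truth."""
    config.validate()
    rate = config.rate
    dt = 1.0 / rate
    geo = _segment_geometry(config.height)
    g = GRAVITY

    # --- phase boundaries and events -------------------------------------
    order = ["zeroing", "calibration", "first_normal", "perturbation",
             "second_normal", "unloaded"]
    bounds = np.concatenate([[0.0], np.cumsum([config.phases[p] for p in order])])
    t_total = bounds[-1]
    n = int(round(t_total * rate))
    t = np.arange(n) * dt
    event_times = {letter: bounds[i] for i, letter in enumerate(PHASE_EVENTS)}
    t_walk0, t_walk1 = event_times["C"], event_times["F"]

    # --- belt speed -------------------------------------------------------
    belt = np.zeros(n)
    walking = (t >= t_walk0 - 1e-9) & (t < t_walk1 - 1e-9)
    belt[walking] = config.nominal_speed
    if config.perturbation is not None and config.phases["perturbation"] > 0:
        params = replace(
            config.perturbation,
            mean_speed=config.nominal_speed,
            duration=config.phases["perturbation"],
            rate=rate,
            seed=config.seed,
        )
        sig = generate_belt_signal(params)
        pert = (t >= event_times["D"] - 1e-9) & (t < event_times["E"] - 1e-9)
        belt[pert] = sig.speed[: int(np.count_nonzero(pert))]

    # --- stride schedule --------------------------------------------------
    if t_walk1 - t_walk0 > 0:
        min_T = stride_length_law(config.nominal_speed) / max(config.nominal_speed, 1e-6)
        if t_walk1 - t_walk0 < 2.0 * min_T:
            raise ValueError(
                f"walking window {t_walk1 - t_walk0:.1f} s too short for the "
                f"{min_T:.2f} s stride period"
            )
    hs_right = []
    durations = []
    speeds_at_hs = []
    tk = t_walk0
    while tk < t_walk1 - 1e-9:
        vk = float(np.interp(tk, t, belt))
        vk = max(vk, 0.1)  # belts are clipped at zero; keep the schedule finite
        Tk = float(stride_length_law(vk)) / vk
        hs_right.append(tk)
        durations.append(Tk)
        speeds_at_hs.append(vk)
        tk += Tk
    hs_right = np.asarray(hs_right)
    durations = np.asarray(durations)
    speeds_at_hs = np.asarray(speeds_at_hs)
    widths = stride_width_law(speeds_at_hs, config.nominal_speed)

    # global stride phase, piecewise linear in time
    phi = np.zeros(n)
    phidot = np.zeros(n)
    idx = np.clip(np.searchsorted(hs_right, t, side="right") - 1, 0, len(hs_right) - 1)
    in_walk = walking
    phi[in_walk] = idx[in_walk] + (t[in_walk] - hs_right[idx[in_walk]]) / durations[idx[in_walk]]
    phidot[in_walk] = 1.0 / durations[idx[in_walk]]

    # truth gait landmarks (only those inside the walking window)
    hs_left = hs_right + 0.5 * durations
    to_right = hs_right + DUTY_FACTOR * durations
    # the left stance that began in the previous stride ends at 10% of this one
    to_left = hs_right + (DUTY_FACTOR - 0.5) * durations
    clip_win = lambda a: a[(a >= t_walk0) & (a < t_walk1)]

    # --- sagittal kinematics ---------------------------------------------
    # Complex sagittal coordinates z + i y.  Rotation about +X multiplies by
    # exp(-i angle); the "down" unit vector is -i.
    sway_z = sum(a * np.sin(2 * np.pi * f * t) for a, f in STANDING_SWAY[:1])
    sway_y = sum(a * np.sin(2 * np.pi * f * t + 1.0) for a, f in STANDING_SWAY[1:])
    sway = sway_z + 1j * sway_y
    sway_dd = sum(-a * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
                  for a, f in STANDING_SWAY[:1]) + 1j * sum(
        -a * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t + 1.0)
        for a, f in STANDING_SWAY[1:])

    hip_base = 1j * geo["hip_height"]
    hip = hip_base + sway
    hip_dd = sway_dd.copy()
    hz, by = HIP_SWAY_Z, HIP_BOB_Y
    hip[in_walk] += hz.val(phi[in_walk]) + 1j * by.val(phi[in_walk])
    hip_dd[in_walk] += (hz.d2(phi[in_walk]) + 1j * by.d2(phi[in_walk])) * phidot[in_walk] ** 2

    shoulder = hip + 1j * geo["trunk"]
    shoulder_dd = hip_dd

    Lt, Ls, Lf = geo["thigh"], geo["shank"], geo["foot"]
    cols: dict[str, np.ndarray] = {}
    truth_cols: dict[str, np.ndarray] = {}
    leg_points: dict = {}

    for side, offset in (("Right", 0.0), ("Left", 0.5)):
        ph = np.where(in_walk, phi + offset, 0.0)
        # joint angles and their time derivatives
        th = {}
        for name, series in GAIT_ANGLES.items():
            standing_val = np.pi / 2.0 if name == "ankle" else 0.0
            val = np.where(in_walk, series.val(ph), standing_val)
            d1 = np.where(in_walk, series.d1(ph) * phidot, 0.0)
            d2 = np.where(in_walk, series.d2(ph) * phidot**2, 0.0)
            th[name] = (val, d1, d2)

        th1, th1d, th1dd = th["hip"]
        th2 = th1 + th["knee"][0]
        th2d = th1d + th["knee"][1]
        th2dd = th1dd + th["knee"][2]
        th3 = th2 + th["ankle"][0]
        th3d = th2d + th["ankle"][1]
        th3dd = th2dd + th["ankle"][2]

        u1 = -1j * np.exp(-1j * th1)
        u2 = -1j * np.exp(-1j * th2)
        u3 = -1j * np.exp(-1j * th3)
        # time derivatives of direction vectors: u' = -i w u, u'' = (-i a - w^2) u
        u1_dd = (-1j * th1dd - th1d**2) * u1
        u2_dd = (-1j * th2dd - th2d**2) * u2
        u3_dd = (-1j * th3dd - th3d**2) * u3
        u2_d = -1j * th2d * u2
        u3_d = -1j * th3d * u3

        knee = hip + Lt * u1
        knee_dd = hip_dd + Lt * u1_dd
        ankle = knee + Ls * u2
        ankle_dd = knee_dd + Ls * u2_dd
        heel = ankle + HEEL_DROP * u2
        heel_dd = ankle_dd + HEEL_DROP * u2_dd
        toe = heel + Lf * u3
        toe_dd = heel_dd + Lf * u3_dd

        leg_points[side] = {
            "shoulder": shoulder, "hip": hip, "hip_dd": hip_dd,
            "knee": knee, "knee_dd": knee_dd,
            "ankle": ankle, "ankle_dd": ankle_dd,
            "heel": heel, "toe": toe, "toe_dd": toe_dd,
            "foot_vec": toe - ankle,
            "foot_vec_d": HEEL_DROP * u2_d + Lf * u3_d,
            "foot_vec_dd": HEEL_DROP * u2_dd + Lf * u3_dd,
            "th2dd": th2dd, "th1dd": th1dd,
            "phase": ph,
        }

        # truth angles and rates (the pose convention recovers exactly these)
        truth_cols[f"{side} Hip Angle"] = th1
        truth_cols[f"{side} Hip Rate"] = th1d
        truth_cols[f"{side} Knee Angle"] = th["knee"][0]
        truth_cols[f"{side} Knee Rate"] = th["knee"][1]
        truth_cols[f"{side} Ankle Angle"] = th["ankle"][0]
        truth_cols[f"{side} Ankle Rate"] = th["ankle"][1]

    # --- lateral (X) marker placement ------------------------------------
    if len(hs_right):
        node_t = np.concatenate([[0.0], hs_right, [t_total]])
        node_w = np.concatenate([[widths[0]], widths, [widths[-1]]])
        w_t = np.interp(t, node_t, node_w)
    else:
        w_t = np.full(n, stride_width_law(config.nominal_speed, config.nominal_speed))

    # --- ground reaction loads -------------------------------------------
    weight = config.mass * g
    amp = weight / (2.0 * DUTY_FACTOR * _GRF_SHAPE_INTEGRAL)
    calibration = (t >= event_times["B"] - 1e-9) & (t < event_times["C"] - 1e-9)

    forces: dict = {}
    for side, plate in (("Left", 1), ("Right", 2)):
        ph = leg_points[side]["phase"]
        frac = np.mod(ph, 1.0)
        stance = in_walk & (frac < DUTY_FACTOR)
        u = np.where(stance, frac / DUTY_FACTOR, 0.0)
        fy = np.where(stance, amp * _grf_shape(u), 0.0)
        fz = np.where(stance, FORE_AFT_AMPLITUDE * weight * np.sin(2 * np.pi * u), 0.0)
        heel_z = leg_points[side]["heel"].real
        toe_z = leg_points[side]["toe"].real
        cop_z = np.where(stance, (1.0 - u) * heel_z + u * toe_z, 0.0)
        ankle_z = leg_points[side]["ankle"].real
        # calibration pose: body weight split evenly, CoP under the ankle
        fy = np.where(calibration, weight / 2.0, fy)
        cop_z = np.where(calibration, ankle_z, cop_z)
        sign = 1.0 if side == "Right" else -1.0
        cop_x = np.where(fy > 0, sign * w_t / 2.0, 0.0)
        forces[side] = {"fy": fy, "fz": fz, "cop_z": cop_z, "cop_x": cop_x}
        cols[f"FP{plate}.ForX"] = np.zeros(n)
        cols[f"FP{plate}.ForY"] = fy
        cols[f"FP{plate}.ForZ"] = fz
        cols[f"FP{plate}.MomX"] = cop_z * fy
        cols[f"FP{plate}.MomY"] = np.zeros(n)
        cols[f"FP{plate}.MomZ"] = -cop_x * fy
        cols[f"FP{plate}.CopX"] = cop_x
        cols[f"FP{plate}.CopY"] = np.zeros(n)
        cols[f"FP{plate}.CopZ"] = cop_z

    # --- segment parameters and truth torques ----------------------------
    foot_len = float(np.mean(np.abs(leg_points["Right"]["foot_vec"])))
    seg_params = default_segment_params(
        config.mass, {"thigh": Lt, "shank": Ls, "foot": foot_len}
    )

    for side in ("Left", "Right"):
        lp = leg_points[side]
        pts, accs, angaccs = {}, {}, {}
        pts[(side, "hip")] = lp["hip"]
        pts[(side, "knee")] = lp["knee"]
        pts[(side, "ankle")] = lp["ankle"]
        for seg, (p0, p0dd, v, vdd) in {
            "thigh": (lp["hip"], lp["hip_dd"], lp["knee"] - lp["hip"],
                      lp["knee_dd"] - lp["hip_dd"]),
            "shank": (lp["knee"], lp["knee_dd"], lp["ankle"] - lp["knee"],
                      lp["ankle_dd"] - lp["knee_dd"]),
            "foot": (lp["ankle"], lp["ankle_dd"], lp["foot_vec"],
                     lp["foot_vec_dd"]),
        }.items():
            fracc = seg_params.segments[(side, seg)]["com_fraction"]
            pts[(side, seg)] = p0 + fracc * v
            accs[(side, seg)] = p0dd + fracc * vdd
        # angular accelerations about +X: psi = -arg(segment vector)
        angaccs[(side, "thigh")] = lp["th1dd"]
        angaccs[(side, "shank")] = lp["th2dd"]
        vf, vfd, vfdd = lp["foot_vec"], lp["foot_vec_d"], lp["foot_vec_dd"]
        angaccs[(side, "foot")] = -np.imag(vfdd / vf - (vfd / vf) ** 2)

        f = forces[side]
        force_c = f["fz"] + 1j * f["fy"]
        cop_c = f["cop_z"].astype(complex)
        torques = newton_euler_leg(pts, accs, angaccs, force_c, cop_c,
                                   seg_params, side)
        for joint in ("Hip", "Knee", "Ankle"):
            truth_cols[f"{side} {joint} Torque"] = torques[joint]

    # --- marker columns ---------------------------------------------------
    for side in ("Left", "Right"):
        p = side[0]
        sign = 1.0 if side == "Right" else -1.0
        lp = leg_points[side]
        sag = {
            "SHO": lp["shoulder"], "GTRO": lp["hip"], "LEK": lp["knee"],
            "LM": lp["ankle"], "HEE": lp["heel"], "TOE": lp["toe"],
        }
        for label, series in sag.items():
            x = sign * (0.18 if label == "SHO" else w_t / 2.0)
            cols[f"{p}{label}.PosX"] = np.broadcast_to(x, (n,)).astype(float)
            cols[f"{p}{label}.PosY"] = series.imag
            cols[f"{p}{label}.PosZ"] = series.real

    # --- assemble tables --------------------------------------------------
    # Buffering occasionally delays a frame's receipt time stamp; most
    # frames arrive on the exact camera clock, which keeps the median
    # inter-frame interval (and hence the inferred rate) exact.
    rng = np.random.default_rng(config.seed + 1)
    jitter = np.where(rng.random(n) < 0.05, rng.uniform(5e-4, 3e-3, n), 0.0)
    jitter[0] = 0.0
    mocap = pd.DataFrame({"TimeStamp": t + jitter,
                          "FrameNumber": np.arange(1, n + 1)} | cols)
    record = pd.DataFrame({"Time": t, "RightBeltSpeed": belt,
                           "LeftBeltSpeed": belt})
    events = EventTimeline(
        Event(letter, trial_io.DEFAULT_EVENTS[letter], event_times[letter])
        for letter in PHASE_EVENTS
    )
    meta = MetaData(
        study={"id": 1, "name": "Synthetic planar walking",
               "description": "Prescribed planar walker with ground truth."},
        subject={"id": config.subject_id, "age": 25, "gender": "NA",
                 "mass": float(config.mass), "mass-units": "kilograms",
                 "height": float(config.height), "height-units": "meters"},
        trial={
            "id": config.trial_id, "subject-id": config.subject_id,
            "datetime": "2015-01-01",
            "nominal-speed": float(config.nominal_speed),
            "nominal-speed-units": "meters per second",
            "stationary-platform": True, "pitch": False, "sway": False,
            "dflow-version": config.dflow_version,
            "cortex-version": "3.1.1.1290", "marker-set": "full",
            "events": dict(trial_io.DEFAULT_EVENTS),
            "files": {},
        },
    )
    bundle = TrialBundle(meta=meta, mocap=mocap, record=record, events=events)

    truth = GroundTruth(
        mass=config.mass,
        events={e.name: e.time for e in events},
        heel_strikes={"right": clip_win(hs_right), "left": clip_win(hs_left)},
        toe_offs={"right": clip_win(to_right), "left": clip_win(to_left)},
        joint_traces=pd.DataFrame(truth_cols, index=pd.Index(t, name="Time")),
        segment_params=seg_params,
        stride_schedule=pd.DataFrame({
            "start": hs_right, "duration": durations,
            "speed": speeds_at_hs, "width": widths,
        }),
        config=config,
    )
    return bundle, truth


def corrupt(bundle: TrialBundle, config: SynthConfig) -> tuple[TrialBundle, dict]:
    """Add measurement noise and missing-marker corruption.

    Gaussian noise goes on marker and load columns; marker frames are then
    marked missing in the dialect matching ``config.dflow_version``: signed
    zeros for new recording-software versions, held previous values (runs of
    3-6 frames) for old ones.  Returns the corrupted bundle and a log of
    missing frame indices per marker.
    """
    from gaitkit.cleaning import marker_labels, uses_signed_zero_dialect

    rng = np.random.default_rng(config.seed + 2)
    mocap = bundle.mocap.copy()
    n = len(mocap)
    labels = marker_labels(mocap)
    if config.marker_noise > 0:
        for label in labels:
            for ax in "XYZ":
                mocap[f"{label}.Pos{ax}"] += rng.normal(0, config.marker_noise, n)
    if config.force_noise > 0:
        for col in mocap.columns:
            if ".For" in col or ".Mom" in col:
                mocap[col] += rng.normal(0, config.force_noise, n)
    log: dict = {}
    if config.missing_rate > 0:
        new_dialect = uses_signed_zero_dialect(config.dflow_version)
        for label in labels:
            axes = [f"{label}.Pos{ax}" for ax in "XYZ"]
            if new_dialect:
                miss = rng.random(n) < config.missing_rate
                miss[0] = False
                signs = rng.choice([0.0, -0.0], size=(int(miss.sum()), 3))
                for j, ax in enumerate(axes):
                    vals = mocap[ax].to_numpy(dtype=float)
                    vals[miss] = signs[:, j]
                    mocap[ax] = vals
                frames = np.flatnonzero(miss)
            else:
                mean_run = 4.5
                starts = rng.random(n) < config.missing_rate / mean_run
                miss = np.zeros(n, dtype=bool)
                for i in np.flatnonzero(starts):
                    run = int(rng.integers(3, 7))
                    if 1 <= i and i + run <= n:
                        miss[i : i + run] = True
                vals = mocap[axes].to_numpy(dtype=float)
                for i in np.flatnonzero(miss):
                    vals[i] = vals[i - 1]
                mocap[axes] = vals
                frames = np.flatnonzero(miss)
            log[label] = frames
    out = TrialBundle(meta=bundle.meta, mocap=mocap, record=bundle.record,
                      events=bundle.events)
    return out, log


def emit(
    bundle: TrialBundle,
    truth: GroundTruth,
    directory: str | os.PathLike,
) -> dict:
    """Write the trial directory plus a ground-truth sidecar HDF5 file."""
    files = trial_io.write_trial(bundle, directory)
    trial_id = bundle.meta.trial_id
    truth_path = Path(directory) / f"T{trial_id:03d}" / f"truth-{trial_id:03d}.h5"
    truth.save(truth_path)
    files["truth"] = str(truth_path)
    return files


def make_trial(
    config: SynthConfig, directory: str | os.PathLike | None = None
) -> tuple[TrialBundle, GroundTruth]:
    """Simulate, corrupt per the config, and optionally emit a trial."""
    bundle, truth = simulate_gait(config)
    if config.missing_rate > 0 or config.marker_noise > 0 or config.force_noise > 0:
        bundle, _ = corrupt(bundle, config)
    if directory is not None:
        emit(bundle, truth, directory)
    return bundle, truth
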