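"""Sagittal-plane joint kinematics and link-segment inverse dynamics.

The lab frame has X pointing right, Y up and Z backward (the subject walks
in -Z).  Sagittal analysis drops X and works in the (Z, Y) plane, which is
represented internally by the complex number ``z + i y``.  A rotation by a
positive angle about the lab +X axis (right-hand rule) maps ``v`` to
``v * exp(-i a)`` in this representation.

Joint angles follow the aligned-configuration convention: hip, knee and
ankle angles are all zero when the shoulder-to-hip, hip-to-knee,
knee-to-ankle and heel-to-toe vectors are aligned, and each angle is the
signed rotation about +X carrying the proximal vector onto the distal one.
With the subject standing straight and the foot flat, hip and knee are zero
and the ankle sits at +pi/2.

Inverse dynamics runs a planar Newton-Euler recursion per leg from the foot
upward: the ground reaction force is applied at the measured center of
pressure, each segment's center-of-mass acceleration and angular
acceleration come from low-pass filtered, twice-differentiated marker
kinematics, and the net internal joint torque about +X is reported at the
ankle, knee and hip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from gaitkit.cleaning import GRAVITY, COP_FORCE_THRESHOLD, CleanTrial

__all__ = [
    "SegmentParams",
    "PlanarPose",
    "JointTraces",
    "WINTER_TABLE",
    "default_segment_params",
    "sagittal_pose",
    "joint_kinematics",
    "inverse_dynamics",
    "newton_euler_leg",
]

SIDES = ("Left", "Right")
JOINTS = ("Hip", "Knee", "Ankle")

#: Markers each leg needs, with L/R prefixes: shoulder, greater trochanter
#: (hip), lateral knee epicondyle, lateral malleolus (ankle), heel, toe.
LEG_MARKERS = ("SHO", "GTRO", "LEK", "LM", "HEE", "TOE")

#: Classic proportional link-segment table: per segment, (mass fraction of
#: body mass, COM position as fraction of segment length from the proximal
#: end, radius of gyration about the COM as fraction of length).
WINTER_TABLE = {
    "foot": (0.0145, 0.50, 0.475),
    "shank": (0.0465, 0.433, 0.302),
    "thigh": (0.100, 0.433, 0.323),
}


@dataclass
class SegmentParams:
    """Lumped inertial parameters of the planar leg segments.

    ``segments`` maps ``(side, name)`` to a dict with ``mass`` (kg),
    ``com_fraction`` (of segment length from the proximal end),
    ``gyration_fraction`` (of length, about the COM) and ``length`` (m).
    """

    total_mass: float
    segments: dict = field(default_factory=dict)
    gravity: float = GRAVITY

    def mass(self, side: str, name: str) -> float:
        return self.segments[(side, name)]["mass"]

    def inertia(self, side: str, name: str) -> float:
        s = self.segments[(side, name)]
        return s["mass"] * (s["gyration_fraction"] * s["length"]) ** 2


def default_segment_params(
    total_mass: float, lengths: dict, table: dict | None = None
) -> SegmentParams:
    """Build segment parameters from a proportional anthropometric table.

    ``lengths`` maps segment names (``foot``, ``shank``, ``thigh``) or
    ``(side, name)`` pairs to segment lengths in meters.  ``table`` may
    override :data:`WINTER_TABLE` entry-by-entry with
    ``(mass_fraction, com_fraction, gyration_fraction)`` tuples.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    tab = dict(WINTER_TABLE)
    if table:
        tab.update(table)
    params = SegmentParams(total_mass=total_mass)
    for side in SIDES:
        for name, (mass_frac, com_frac, gyr_frac) in tab.items():
            length = lengths.get((side, name), lengths.get(name))
            if length is None:
                raise KeyError(f"no length given for segment {name!r}")
            if length <= 0:
                raise ValueError(f"segment {name!r} has non-positive length {length}")
            params.segments[(side, name)] = {
                "mass": mass_frac * total_mass,
                "com_fraction": com_frac,
                "gyration_fraction": gyr_frac,
                "length": float(length),
            }
    return params


# ---------------------------------------------------------------------------
# pose extraction
# ---------------------------------------------------------------------------

def _complex_marker(data: pd.DataFrame, label: str) -> np.ndarray:
    """Sagittal projection of a marker as z + i y."""
    zcol, ycol = f"{label}.PosZ", f"{label}.PosY"
    for col in (zcol, ycol):
        if col not in data.columns:
            raise KeyError(f"required marker column {col!r} missing")
    return data[zcol].to_numpy(dtype=float) + 1j * data[ycol].to_numpy(dtype=float)


def signed_angle(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Signed rotation about lab +X carrying sagittal vector u onto w.

    Vectors are complex ``z + i y``; rotation by ``a`` about +X multiplies by
    ``exp(-i a)``, so the angle is ``arg(u) - arg(w)`` wrapped to (-pi, pi].
    """
    a = np.angle(u) - np.angle(w)
    return (a + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class PlanarPose:
    """Per-frame sagittal joint points and angles for both legs.

    ``points[(side, name)]`` are complex ``z + i y`` series for shoulder,
    hip, knee, ankle, heel and toe; ``angles`` has columns
    ``"<Side> <Joint> Angle"`` in radians.
    """

    time: np.ndarray
    points: dict
    angles: pd.DataFrame

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


def sagittal_pose(trial: CleanTrial | pd.DataFrame) -> PlanarPose:
    """Project leg markers onto the sagittal plane and compute joint angles."""
    if isinstance(trial, CleanTrial):
        data, time = trial.data, trial.time
    else:
        data = trial
        time = data.index.to_numpy(dtype=float)
    points: dict = {}
    angle_cols = {}
    for side in SIDES:
        p = side[0]
        sho = _complex_marker(data, f"{p}SHO")
        hip = _complex_marker(data, f"{p}GTRO")
        knee = _complex_marker(data, f"{p}LEK")
        ankle = _complex_marker(data, f"{p}LM")
        heel = _complex_marker(data, f"{p}HEE")
        toe = _complex_marker(data, f"{p}TOE")
        points.update({
            (side, "shoulder"): sho, (side, "hip"): hip, (side, "knee"): knee,
            (side, "ankle"): ankle, (side, "heel"): heel, (side, "toe"): toe,
        })
        angle_cols[f"{side} Hip Angle"] = signed_angle(hip - sho, knee - hip)
        angle_cols[f"{side} Knee Angle"] = signed_angle(knee - hip, ankle - knee)
        angle_cols[f"{side} Ankle Angle"] = signed_angle(ankle - knee, toe - heel)
    angles = pd.DataFrame(angle_cols, index=pd.Index(time, name="Time"))
    return PlanarPose(time=np.asarray(time, dtype=float), points=points, angles=angles)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase (forward-backward) second-order Butterworth low-pass."""
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz at or above Nyquist ({rate / 2} Hz)")
    b, a = butter(2, cutoff / (rate / 2.0), "lowpass")
    return filtfilt(b, a, x)


def joint_kinematics(
    pose: PlanarPose, cutoff: float = 6.0, rate: float | None = None
) -> pd.DataFrame:
    """Filtered joint angles and their rates.

    Angles are unwrapped and zero-phase low-pass filtered; rates are central
    differences of the filtered angles (one-sided at the endpoints).
    Returns ``"<Side> <Joint> Angle"`` and ``"... Rate"`` columns.
    """
    rate = rate or pose.rate
    dt = 1.0 / rate
    out = {}
    for col in pose.angles.columns:
        theta = np.unwrap(pose.angles[col].to_numpy(dtype=float))
        theta_f = _lowpass(theta, cutoff, rate)
        out[col] = theta_f
        out[col.replace("Angle", "Rate")] = np.gradient(theta_f, dt)
    return pd.DataFrame(out, index=pose.angles.index)


# ---------------------------------------------------------------------------
# inverse dynamics
# ---------------------------------------------------------------------------

def _cross(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    # moment about +X of planar force f at position r: M_x = r_y F_z - r_z F_y
    return r.imag * f.real - r.real * f.imag


def newton_euler_leg(
    points: dict,
    accels: dict,
    ang_accels: dict,
    grf_force: np.ndarray,
    grf_cop: np.ndarray,
    params: SegmentParams,
    side: str,
) -> dict:
    """Planar Newton-Euler recursion from the foot up for one leg.

    ``points``/``accels`` hold complex ``z + i y`` positions and COM
    accelerations keyed ``(side, segment)`` for ``foot``/``shank``/``thigh``
    plus joint points ``(side, ankle|knee|hip)``; ``ang_accels`` holds
    angular accelerations about +X per segment.  ``grf_force`` is the
    complex external force on the foot applied at ``grf_cop``.  Returns
    joint torque arrays keyed ``Ankle``/``Knee``/``Hip``.

    Shared by the measurement pipeline (numerical derivatives) and the
    synthetic ground-truth generator (analytic derivatives), so the two
    paths differ only in how the accelerations were obtained.
    """
    g = params.gravity
    chain = (("foot", "ankle"), ("shank", "knee"), ("thigh", "hip"))
    torques = {}
    f_dist = grf_force
    p_dist = grf_cop
    tau_dist = np.zeros(np.shape(grf_force), dtype=float)
    for seg, joint in chain:
        m = params.mass(side, seg)
        inertia = params.inertia(side, seg)
        com = points[(side, seg)]
        p_prox = points[(side, joint)]
        weight = -1j * m * g
        f_prox = m * accels[(side, seg)] - weight - f_dist
        tau_prox = (
            inertia * ang_accels[(side, seg)]
            - tau_dist
            - _cross(p_dist - com, f_dist)
            - _cross(p_prox - com, f_prox)
        )
        torques[joint.capitalize()] = tau_prox
        # reaction on the next segment up
        f_dist = -f_prox
        tau_dist = -tau_prox
        p_dist = p_prox
    return torques


def segment_com_points(points_prox_dist: dict, params: SegmentParams, side: str):
    """COM positions from proximal/distal endpoint series and COM fractions."""
    out = {}
    for seg, (prox, dist) in points_prox_dist.items():
        frac = params.segments[(side, seg)]["com_fraction"]
        out[seg] = prox + frac * (dist - prox)
    return out


def inverse_dynamics(
    trial: CleanTrial,
    params: SegmentParams,
    cutoff: float = 6.0,
    stance_threshold: float = COP_FORCE_THRESHOLD,
) -> "JointTraces":
    """2D link-segment inverse dynamics for both legs.

    Plate 1 loads the left foot, plate 2 the right.  Samples whose vertical
    GRF is below ``stance_threshold`` are treated as swing: the external
    load is set exactly to zero so plate noise cannot leak into swing
    torques.  Marker kinematics are zero-phase low-pass filtered at
    ``cutoff`` before double differentiation; the raw plate loads are used
    as measured.
    """
    pose = sagittal_pose(trial)
    rate = pose.rate
    dt = 1.0 / rate

    def filt_c(z):
        return _lowpass(z.real, cutoff, rate) + 1j * _lowpass(z.imag, cutoff, rate)

    def accel_c(z):
        return (np.gradient(np.gradient(z.real, dt), dt)
                + 1j * np.gradient(np.gradient(z.imag, dt), dt))

    out = dict(joint_kinematics(pose, cutoff=cutoff, rate=rate))

    for side, plate in (("Left", 1), ("Right", 2)):
        hip = filt_c(pose.points[(side, "hip")])
        knee = filt_c(pose.points[(side, "knee")])
        ankle = filt_c(pose.points[(side, "ankle")])
        toe = filt_c(pose.points[(side, "toe")])

        points = {(side, "hip"): hip, (side, "knee"): knee, (side, "ankle"): ankle}
        accels, ang_accels = {}, {}
        for seg, (prox, dist) in (("thigh", (hip, knee)), ("shank", (knee, ankle)),
                                  ("foot", (ankle, toe))):
            frac = params.segments[(side, seg)]["com_fraction"]
            com = prox + frac * (dist - prox)
            points[(side, seg)] = com
            accels[(side, seg)] = accel_c(com)
            psi = -np.unwrap(np.angle(dist - prox))
            ang_accels[(side, seg)] = np.gradient(np.gradient(psi, dt), dt)

        fy_col = f"FP{plate}.ForY"
        if fy_col not in trial.data.columns:
            raise KeyError(f"vertical force column {fy_col!r} missing")
        fy = trial.data[fy_col].to_numpy(dtype=float)
        fz = trial.data.get(f"FP{plate}.ForZ")
        fz = fz.to_numpy(dtype=float) if fz is not None else np.zeros_like(fy)
        cop_z = trial.data.get(f"FP{plate}.CopZ")
        cop_z = cop_z.to_numpy(dtype=float) if cop_z is not None else np.zeros_like(fy)
        stance = fy >= stance_threshold
        force = np.where(stance, fz, 0.0) + 1j * np.where(stance, fy, 0.0)
        cop = np.where(stance, np.nan_to_num(cop_z), 0.0).astype(complex)

        torques = newton_euler_leg(points, accels, ang_accels, force, cop,
                                   params, side)
        for joint in JOINTS:
            out[f"{side} {joint} Torque"] = torques[joint]

    traces = pd.DataFrame(out, index=pose.angles.index)
    return JointTraces(data=traces, cutoff=cutoff)


@dataclass
class JointTraces:
    """Joint angle, rate and torque series per leg and joint.

    Columns follow ``"<Side> <Joint> Angle|Rate|Torque"``.
    """

    data: pd.DataFrame
    cutoff: float = 6.0

    def save(self, path, key: str = "joint_traces") -> None:
        self.data.to_hdf(path, key=key, mode="a")

    @classmethod
    def load(cls, path, key: str = "joint_traces") -> "JointTraces":
        return cls(data=pd.read_hdf(path, key=key))
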