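"""Sagittal pose extraction, joint kinematics and inverse dynamics."""

import numpy as np
import pandas as pd
import pytest

from gaitkit.cleaning import CleanTrial, GRAVITY
from gaitkit.dynamics2d import (
    PlanarPose,
    default_segment_params,
    inverse_dynamics,
    joint_kinematics,
    sagittal_pose,
    signed_angle,
)
from gaitkit.trial_io import EventTimeline


def leg_marker_frame(n=1, shank_rotation=0.0, x_offset=0.0):
    """Marker table for a straight-legged figure; optionally rotate the
    shank about +X by the given angle (ankle and foot follow the shank)."""
    # aligned nominal: shoulder->hip->knee->ankle all along -Y, heel->toe too
    rows = {}
    th = shank_rotation
    # rotation about +X in (z, y): (z, y) -> (z cos a + y sin a, y cos a - z sin a)
    def rot(z, y):
        return z * np.cos(th) + y * np.sin(th), y * np.cos(th) - z * np.sin(th)

    knee = np.array([0.0, 0.55])  # (z, y)
    shank_vec = (0.0, -0.45)
    dz, dy = rot(*shank_vec)
    ankle = knee + [dz, dy]
    # the foot keeps its nominal (downward) orientation; only the shank is
    # rotated, so the ankle angle should read the negative shank rotation
    heel = ankle + 0.05 * np.array([0.0, -1.0])
    toe = heel + 0.2 * np.array([0.0, -1.0])
    pts = {"SHO": (0.0, 1.45), "GTRO": (0.0, 1.0), "LEK": tuple(knee),
           "LM": tuple(ankle), "HEE": tuple(heel), "TOE": tuple(toe)}
    for side in "LR":
        for label, (z, y) in pts.items():
            rows[f"{side}{label}.PosX"] = np.full(n, x_offset)
            rows[f"{side}{label}.PosY"] = np.full(n, y)
            rows[f"{side}{label}.PosZ"] = np.full(n, z)
    return pd.DataFrame(rows, index=pd.Index(np.arange(n) * 0.01, name="Time"))


class TestSagittalPose:
    def test_aligned_configuration_zero_angles(self):
        pose = sagittal_pose(leg_marker_frame())
        assert np.allclose(pose.angles.to_numpy(), 0.0, atol=1e-12)

    def test_shank_rotation_maps_to_knee_and_ankle(self):
        pose = sagittal_pose(leg_marker_frame(shank_rotation=0.3))
        row = pose.angles.iloc[0]
        assert row["Right Knee Angle"] == pytest.approx(0.3)
        assert row["Right Ankle Angle"] == pytest.approx(-0.3)
        assert row["Right Hip Angle"] == pytest.approx(0.0)

    def test_x_translation_invariance(self):
        a = sagittal_pose(leg_marker_frame()).angles
        b = sagittal_pose(leg_marker_frame(x_offset=0.4)).angles
        pd.testing.assert_frame_equal(a, b)

    def test_missing_marker_named(self):
        df = leg_marker_frame().drop(columns=["RLM.PosZ"])
        with pytest.raises(KeyError, match="RLM.PosZ"):
            sagittal_pose(df)

    def test_signed_angle_convention(self):
        # rotating -i (down) by +pi/2 about +X gives -1 (backward, +Z... -Z?)
        u = np.array([-1j])
        w = u * np.exp(-1j * 0.4)
        assert signed_angle(u, w)[0] == pytest.approx(0.4)


class TestJointKinematics:
    def make_pose(self, theta):
        n = len(theta)
        t = np.arange(n) * 0.01
        angles = pd.DataFrame(
            {f"{s} {j} Angle": theta for s in ("Left", "Right")
             for j in ("Hip", "Knee", "Ankle")},
            index=pd.Index(t, name="Time"))
        return PlanarPose(time=t, points={}, angles=angles)

    def test_constant_angle_zero_rate(self):
        kin = joint_kinematics(self.make_pose(np.full(200, 0.7)))
        assert np.allclose(kin["Right Hip Rate"], 0.0, atol=1e-9)

    def test_sine_rate_amplitude(self):
        t = np.arange(1000) * 0.01
        kin = joint_kinematics(self.make_pose(np.sin(2 * np.pi * t)))
        mid = kin["Right Hip Rate"].to_numpy()[200:800]
        assert mid.max() == pytest.approx(2 * np.pi, rel=0.01)

    def test_high_frequency_noise_rejected(self):
        t = np.arange(1000) * 0.01
        clean = np.sin(2 * np.pi * t)
        noisy = clean + 0.01 * np.sin(2 * np.pi * 30.0 * t)
        a = joint_kinematics(self.make_pose(clean))["Right Hip Rate"].iloc[200:800]
        b = joint_kinematics(self.make_pose(noisy))["Right Hip Rate"].iloc[200:800]
        assert abs(b.max() - a.max()) / a.max() < 0.02

    def test_cutoff_above_nyquist(self):
        with pytest.raises(ValueError):
            joint_kinematics(self.make_pose(np.zeros(100)), cutoff=80.0)


def static_trial(n=400, mass=70.0, cop_offset=0.0):
    """Standing still: straight legs, feet flat, constant mg/2 per plate."""
    markers = leg_marker_frame(n)
    # flatten the feet: heel below the ankle, toe forward (-Z)
    for side in "LR":
        markers[f"{side}HEE.PosZ"] = 0.0
        markers[f"{side}HEE.PosY"] = 0.06
        markers[f"{side}TOE.PosZ"] = -0.2
        markers[f"{side}TOE.PosY"] = 0.06
    ankle_z = float(markers["RLM.PosZ"].iloc[0])
    data = markers.copy()
    for plate in (1, 2):
        data[f"FP{plate}.ForY"] = mass * GRAVITY / 2.0
        data[f"FP{plate}.ForZ"] = 0.0
        data[f"FP{plate}.CopZ"] = ankle_z + cop_offset
    return CleanTrial(data=data, events=EventTimeline())


class TestInverseDynamics:
    def params(self, mass=70.0):
        return default_segment_params(
            mass, {"thigh": 0.45, "shank": 0.45, "foot": 0.21})

    def test_zero_gravity_static_zero_torques(self):
        trial = static_trial()
        for plate in (1, 2):
            trial.data[f"FP{plate}.ForY"] = 0.0
        params = self.params()
        params.gravity = 0.0
        traces = inverse_dynamics(trial, params, stance_threshold=-1.0)
        torque_cols = [c for c in traces.data.columns if "Torque" in c]
        assert np.allclose(traces.data[torque_cols].to_numpy()[50:-50], 0.0,
                           atol=1e-9)

    def test_static_standing_matches_closed_form(self):
        """With the CoP under the ankle, the ankle torque equals the moment
        of the GRF-minus-leg-weight about the ankle generated by the foot
        segment geometry (hand-derived static equilibrium)."""
        mass = 70.0
        trial = static_trial(mass=mass)
        params = self.params(mass)
        traces = inverse_dynamics(trial, params, cutoff=6.0)
        row = traces.data.iloc[200]

        seg = params.segments[("Right", "foot")]
        m_f = seg["mass"]
        # static closed form: F_ankle_y = mg/2 - m_foot g (up), applied at
        # the ankle; torque balances gravity at the foot COM and GRF at CoP
        ankle = complex(trial.data["RLM.PosZ"].iloc[0],
                        trial.data["RLM.PosY"].iloc[0])
        toe = complex(trial.data["RTOE.PosZ"].iloc[0],
                      trial.data["RTOE.PosY"].iloc[0])
        com = ankle + seg["com_fraction"] * (toe - ankle)
        cop = complex(trial.data["FP2.CopZ"].iloc[0], 0.0)
        fy = mass * GRAVITY / 2.0
        f_prox_y = m_f * 0.0 + m_f * GRAVITY - fy
        # tau = -cross(cop - com, F_grf) - cross(ankle - com, F_prox)
        tau = -((cop - com).imag * 0.0 - (cop - com).real * fy) \
            - ((ankle - com).imag * 0.0 - (ankle - com).real * f_prox_y)
        assert row["Right Ankle Torque"] == pytest.approx(tau, abs=1e-6)

    def test_swing_loads_gated_to_zero(self):
        trial = static_trial()
        for plate in (1, 2):
            trial.data[f"FP{plate}.ForY"] = 5.0  # below the 20 N threshold
        traces = inverse_dynamics(trial, self.params())
        # same result as exactly zero plate signal
        for plate in (1, 2):
            trial.data[f"FP{plate}.ForY"] = 0.0
        traces0 = inverse_dynamics(trial, self.params())
        pd.testing.assert_frame_equal(traces.data, traces0.data)

    def test_left_right_symmetry_under_mirroring(self):
        df = leg_marker_frame(300)
        t = df.index.to_numpy()
        # give the right leg some motion, left stays straight
        df["RLEK.PosZ"] = 0.05 * np.sin(2 * np.pi * t)
        data = df.copy()
        for plate in (1, 2):
            data[f"FP{plate}.ForY"] = 400.0
            data[f"FP{plate}.ForZ"] = 0.0
            data[f"FP{plate}.CopZ"] = 0.0
        trial = CleanTrial(data=data, events=EventTimeline())
        mirrored = data.copy()
        for label in ("SHO", "GTRO", "LEK", "LM", "HEE", "TOE"):
            for ax in "XYZ":
                mirrored[f"L{label}.Pos{ax}"] = data[f"R{label}.Pos{ax}"]
                mirrored[f"R{label}.Pos{ax}"] = data[f"L{label}.Pos{ax}"]
        for col in [c for c in data.columns if c.endswith("PosX")]:
            mirrored[col] = -mirrored[col]
        mirror_trial = CleanTrial(data=mirrored, events=EventTimeline())
        a = inverse_dynamics(trial, self.params())
        b = inverse_dynamics(mirror_trial, self.params())
        for joint in ("Hip", "Knee", "Ankle"):
            np.testing.assert_allclose(
                a.data[f"Right {joint} Torque"],
                b.data[f"Left {joint} Torque"], atol=1e-9)


class TestSegmentParams:
    def test_winter_thigh_fraction(self):
        params = default_segment_params(80.0, {"thigh": 0.45, "shank": 0.44,
                                               "foot": 0.2})
        assert params.mass("Left", "thigh") == pytest.approx(8.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            default_segment_params(80.0, {"thigh": 0.0, "shank": 0.44,
                                          "foot": 0.2})

    def test_custom_table_override(self):
        params = default_segment_params(
            80.0, {"thigh": 0.45, "shank": 0.44, "foot": 0.2},
            table={"thigh": (0.12, 0.40, 0.30)})
        assert params.mass("Right", "thigh") == pytest.approx(9.6)
        assert params.segments[("Right", "thigh")]["com_fraction"] == 0.40

    def test_non_positive_mass(self):
        with pytest.raises(ValueError):
            default_segment_params(0.0, {"thigh": 1, "shank": 1, "foot": 1})
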