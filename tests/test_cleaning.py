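"""Missing-marker handling, stream merging, mass and load compensation."""

import numpy as np
import pandas as pd
import pytest

from gaitkit import cleaning
from gaitkit.cleaning import (
    CleanTrial,
    apply_compensation,
    detect_missing,
    extract_event_segment,
    fit_compensation,
    interpolate_missing,
    measured_mass,
    merge_streams,
    CompensationModel,
)
from gaitkit.trial_io import Event, EventTimeline, IntegrityError


def marker_frame(xyz_rows):
    rows = np.asarray(xyz_rows, dtype=float)
    n = len(rows)
    return pd.DataFrame({
        "TimeStamp": np.arange(n) * 0.01,
        "FrameNumber": np.arange(1, n + 1),
        "MK.PosX": rows[:, 0], "MK.PosY": rows[:, 1], "MK.PosZ": rows[:, 2],
    })


class TestDetectMissing:
    def test_signed_zero_dialect(self):
        df = marker_frame([[0.1, 0.2, 0.3], [0.0, -0.0, 0.0], [0.1, 0.2, 0.3]])
        mask = detect_missing(df, "3.16.2rc4")
        assert list(mask.mask["MK"]) == [False, True, False]

    def test_old_dialect_constant_run(self):
        moving = [[i * 0.01, 0.2, 0.3] for i in range(15)]
        for i in range(1, 10):  # frames 1..9 repeat frame 0's values
            moving[i] = list(moving[0])
        mask = detect_missing(marker_frame(moving), "3.16.1")
        expected = [False] + [True] * 9 + [False] * 5
        assert list(mask.mask["MK"]) == expected

    def test_old_dialect_short_run_is_real(self):
        rows = [[0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0.2, 0.2, 0.3]]
        mask = detect_missing(marker_frame(rows), "3.16.1")
        assert not mask.any()

    def test_no_zero_triplets_all_false(self):
        df = marker_frame([[0.1, 0.2, 0.3], [0.2, 0.3, 0.4]])
        assert not detect_missing(df, "3.16.2rc4").any()

    def test_unparseable_version(self):
        with pytest.raises(ValueError, match="dflow-version"):
            detect_missing(marker_frame([[0, 0, 0]]), "new-ish")

    def test_version_ordering(self):
        assert cleaning.uses_signed_zero_dialect("3.16.2")
        assert cleaning.uses_signed_zero_dialect("3.16.2rc4")
        assert not cleaning.uses_signed_zero_dialect("3.16.2rc3")
        assert not cleaning.uses_signed_zero_dialect("3.16.1")


class TestInterpolate:
    def base(self, middle):
        df = marker_frame([[1.0, 1.0, 1.0], [middle] * 3, [3.0, 3.0, 3.0]])
        mask = detect_missing(df, "3.16.2rc4")
        return df, mask

    def test_linear_midpoint(self):
        df, mask = self.base(0.0)
        out = interpolate_missing(df, mask, "linear")
        assert out.loc[1, "MK.PosY"] == pytest.approx(2.0)

    def test_hold_previous(self):
        df, mask = self.base(0.0)
        out = interpolate_missing(df, mask, "hold")
        assert out.loc[1, "MK.PosY"] == pytest.approx(1.0)

    def test_unmasked_samples_bit_identical(self):
        df, mask = self.base(0.0)
        out = interpolate_missing(df, mask, "linear")
        assert out.loc[0, "MK.PosZ"] == df.loc[0, "MK.PosZ"]
        assert out.loc[2, "MK.PosZ"] == df.loc[2, "MK.PosZ"]

    def test_entirely_missing_marker(self):
        df = marker_frame([[0.0] * 3, [0.0] * 3])
        mask = detect_missing(df, "3.16.2rc4")
        with pytest.raises(IntegrityError, match="MK"):
            interpolate_missing(df, mask)

    def test_sine_gap_error_bound(self):
        f, rate = 2.0, 100.0
        t = np.arange(400) / rate
        rng = np.random.default_rng(3)
        clean = 0.1 * np.sin(2 * np.pi * f * t) + 0.5
        df = pd.DataFrame({
            "TimeStamp": t, "FrameNumber": np.arange(1, 401),
            "MK.PosX": clean, "MK.PosY": clean, "MK.PosZ": clean,
        })
        gaps = rng.random(400) < 0.05
        gaps[[0, -1]] = False
        corrupted = df.copy()
        for ax in "XYZ":
            corrupted.loc[gaps, f"MK.Pos{ax}"] = 0.0
        mask = detect_missing(corrupted, "3.16.2rc4")
        out = interpolate_missing(corrupted, mask, "linear")
        # single-frame linear interpolation error bound for a sinusoid
        bound = 2.0 * (2 * np.pi * f / rate) ** 2
        err = np.abs(out["MK.PosY"].to_numpy() - clean)
        assert err.max() < bound * 0.1  # 0.1 m amplitude


def simple_trial(n=200, rate=100.0, events=()):
    t = np.arange(n) / rate
    data = pd.DataFrame({
        "FP1.ForY": np.full(n, 367.875),
        "FP2.ForY": np.full(n, 367.875),
        "RightBeltSpeed": np.full(n, 1.2),
        "LeftBeltSpeed": np.full(n, 1.2),
    }, index=pd.Index(t, name="Time"))
    return CleanTrial(data=data, events=EventTimeline(events))


class TestMergeStreams:
    def mocap_df(self, n=100, rate=100.0):
        t = np.arange(n) / rate
        return pd.DataFrame({
            "TimeStamp": t, "FrameNumber": np.arange(1, n + 1),
            "MK.PosY": np.linspace(0, 1, n),
        })

    def test_identical_grids_concatenate(self):
        mocap = self.mocap_df()
        record = pd.DataFrame({"Time": mocap["TimeStamp"],
                               "RightBeltSpeed": np.linspace(0, 2, 100),
                               "LeftBeltSpeed": np.zeros(100)})
        trial = merge_streams(mocap, record)
        assert trial.rate == pytest.approx(100.0)
        np.testing.assert_allclose(trial.data["RightBeltSpeed"],
                                   np.linspace(0, 2, 100), atol=1e-12)

    def test_fast_record_downsampled_on_ramp(self):
        mocap = self.mocap_df(50, 100.0)
        t_fast = np.arange(150) / 300.0
        record = pd.DataFrame({"Time": t_fast,
                               "RightBeltSpeed": 2.0 * t_fast,
                               "LeftBeltSpeed": np.zeros(150)})
        trial = merge_streams(mocap, record)
        assert trial.rate == pytest.approx(100.0)
        np.testing.assert_allclose(trial.data["RightBeltSpeed"],
                                   2.0 * trial.time, atol=1e-9)

    def test_output_truncated_to_overlap(self):
        mocap = self.mocap_df(100)
        record = pd.DataFrame({"Time": np.arange(30) / 100.0,
                               "RightBeltSpeed": np.ones(30),
                               "LeftBeltSpeed": np.ones(30)})
        trial = merge_streams(mocap, record)
        assert trial.time[-1] <= record["Time"].iloc[-1] + 1e-12

    def test_no_overlap_errors(self):
        mocap = self.mocap_df(10)
        record = pd.DataFrame({"Time": 100.0 + np.arange(10) / 100.0,
                               "RightBeltSpeed": np.ones(10),
                               "LeftBeltSpeed": np.ones(10)})
        with pytest.raises(IntegrityError):
            merge_streams(mocap, record)

    def test_event_count_and_order_conserved(self):
        mocap = self.mocap_df()
        record = pd.DataFrame({"Time": mocap["TimeStamp"],
                               "RightBeltSpeed": np.ones(100),
                               "LeftBeltSpeed": np.ones(100)})
        events = EventTimeline([Event("A", "Force Plate Zeroing", 0.1),
                                Event("B", "Calibration Pose", 0.5)])
        trial = merge_streams(mocap, record, events=events)
        assert [e.letter for e in trial.events] == ["A", "B"]


class TestExtractSegment:
    def trial_with_events(self):
        return simple_trial(events=[
            Event("C", "First Normal Walking", 0.5),
            Event("D", "Longitudinal Perturbation", 1.2),
        ])

    def test_segment_bounds(self):
        seg = extract_event_segment(self.trial_with_events(), "First Normal Walking")
        assert len(seg.data) == 70  # [0.5, 1.2) at 100 Hz
        assert seg.time[0] == pytest.approx(0.0)  # re-based

    def test_last_event_runs_to_end(self):
        seg = extract_event_segment(self.trial_with_events(),
                                    "Longitudinal Perturbation")
        assert len(seg.data) == 80  # [1.2, 2.0)

    def test_unknown_event_lists_available(self):
        with pytest.raises(KeyError, match="First Normal Walking"):
            extract_event_segment(self.trial_with_events(), "Nope")


class TestMeasuredMass:
    def test_constant_force(self):
        trial = simple_trial(events=[Event("B", "Calibration Pose", 0.2)])
        mass, sd = measured_mass(trial)
        assert mass == pytest.approx(75.0)
        assert sd == pytest.approx(0.0)

    def test_zero_force(self):
        trial = simple_trial(events=[Event("B", "Calibration Pose", 0.2)])
        trial.data["FP1.ForY"] = 0.0
        trial.data["FP2.ForY"] = 0.0
        mass, _ = measured_mass(trial)
        assert mass == pytest.approx(0.0)

    def test_noisy_force_sampling_distribution(self):
        rng = np.random.default_rng(7)
        trial = simple_trial(n=300)
        trial.events.append(Event("B", "Calibration Pose", 0.5))
        noise = rng.normal(0, 9.81, 300)
        trial.data["FP1.ForY"] = 367.875 + noise / 2.0
        trial.data["FP2.ForY"] = 367.875 + noise / 2.0
        mass, sd = measured_mass(trial)  # 100 samples in the 1 s window
        assert mass == pytest.approx(75.0, abs=0.35)  # ~3 standard errors
        assert sd == pytest.approx(1.0, rel=0.35)

    def test_missing_event(self):
        with pytest.raises(KeyError):
            measured_mass(simple_trial())


class TestCompensation:
    def unloaded_trial(self, slope=2.0, intercept=0.5, noise=0.05, n=2000):
        rng = np.random.default_rng(5)
        t = np.arange(n) / 100.0
        speed = 1.2 + 0.3 * np.sin(2 * np.pi * 0.5 * t)
        accel = 0.3 * 2 * np.pi * 0.5 * np.cos(2 * np.pi * 0.5 * t)
        data = pd.DataFrame({
            "RightBeltSpeed": speed, "LeftBeltSpeed": speed,
            "FP1.ForY": slope * accel + intercept + rng.normal(0, noise, n),
            "FP2.ForY": np.zeros(n),
            "FP1.MomX": np.zeros(n), "FP1.MomZ": np.zeros(n),
            "FP1.CopX": np.zeros(n), "FP1.CopY": np.zeros(n),
            "FP1.CopZ": np.zeros(n),
        }, index=pd.Index(t, name="Time"))
        return CleanTrial(data=data, events=EventTimeline())

    def test_least_squares_recovery(self):
        model = fit_compensation(self.unloaded_trial())
        slope, intercept = model.coefficients["FP1.ForY"]
        assert slope == pytest.approx(2.0, rel=0.05)
        assert intercept == pytest.approx(0.5, abs=0.02)

    def test_zero_acceleration_pure_intercept(self):
        trial = self.unloaded_trial()
        trial.data["RightBeltSpeed"] = 1.2
        trial.data["LeftBeltSpeed"] = 1.2
        trial.data["FP1.ForY"] = 0.5
        model = fit_compensation(trial)
        assert model.coefficients["FP1.ForY"] == (0.0, pytest.approx(0.5))
        out = apply_compensation(trial, model)
        assert np.allclose(out.data["FP1.ForY"], 0.0, atol=1e-9)

    def test_zero_model_is_identity(self):
        trial = self.unloaded_trial()
        out = apply_compensation(trial, CompensationModel())
        force_cols = [c for c in trial.data.columns if ".For" in c or ".Mom" in c]
        pd.testing.assert_frame_equal(out.data[force_cols], trial.data[force_cols])

    def test_residuals_uncorrelated_with_acceleration(self):
        trial = self.unloaded_trial(noise=0.2)
        model = fit_compensation(trial)
        out = apply_compensation(trial, model)
        accel = cleaning.belt_acceleration(trial, "LeftBeltSpeed")
        resid = out.data["FP1.ForY"].to_numpy()
        r = np.corrcoef(accel, resid)[0, 1]
        assert abs(r) < 0.05


class TestPipelineIdempotence:
    def test_rerunning_merge_changes_nothing(self, unperturbed_run):
        trial = unperturbed_run["trial"]
        mocap = trial.data.reset_index().rename(columns={"Time": "TimeStamp"})
        mocap.insert(1, "FrameNumber", np.arange(1, len(mocap) + 1))
        record = pd.DataFrame({
            "Time": trial.time,
            "RightBeltSpeed": trial.data["RightBeltSpeed"],
            "LeftBeltSpeed": trial.data["LeftBeltSpeed"],
        })
        again = merge_streams(mocap.drop(columns=["RightBeltSpeed", "LeftBeltSpeed"]),
                              record, events=trial.events)
        shared = [c for c in trial.data.columns if c in again.data.columns]
        np.testing.assert_allclose(again.data[shared].to_numpy(),
                                   trial.data[shared].to_numpy(), atol=1e-9)
        assert len(again.events) == len(trial.events)
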