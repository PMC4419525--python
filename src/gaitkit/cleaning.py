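"""Cleaning pipeline for raw treadmill trials.

Turns the two raw streams of a trial into one merged, gap-filled, uniformly
sampled table: missing-marker detection (both acquisition-software dialects),
interpolation, resampling of the belt-speed record onto the mocap grid,
event segmentation, vertical-GRF body mass, and a linear belt-inertia load
compensation model fitted on unloaded (no-subject) trials.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from gaitkit.trial_io import (
    EventTimeline,
    Event,
    IntegrityError,
    MetaData,
    infer_sample_times,
)

__all__ = [
    "MissingMask",
    "CleanTrial",
    "CompensationModel",
    "detect_missing",
    "interpolate_missing",
    "merge_streams",
    "extract_event_segment",
    "measured_mass",
    "fit_compensation",
    "apply_compensation",
    "clean_trial",
]

GRAVITY = 9.81  # m/s^2
COP_FORCE_THRESHOLD = 20.0  # N; below this the center of pressure is undefined

#: First acquisition-software version that encodes missing markers as
#: signed-zero coordinate triplets; older versions hold the last seen value.
SIGNED_ZERO_VERSION = (3, 16, 2, 0, 4)


def parse_dflow_version(version: str) -> tuple:
    """Parse a dotted version with optional ``rc`` suffix into a sortable tuple.

    Release versions sort above their release candidates (``3.16.2`` >
    ``3.16.2rc4``).
    """
    m = re.fullmatch(r"\s*(\d+)\.(\d+)(?:\.(\d+))?(?:rc(\d+))?\s*", str(version))
    if not m:
        raise ValueError(
            f"cannot parse acquisition-software version {version!r}; "
            "correct the dflow-version field in the trial meta file"
        )
    major, minor, patch, rc = m.groups()
    # final releases get rc-rank 1 so that X.Y.ZrcN < X.Y.Z
    return (int(major), int(minor), int(patch or 0), 0 if rc else 1, int(rc or 0))


def uses_signed_zero_dialect(version: str) -> bool:
    return parse_dflow_version(version) >= SIGNED_ZERO_VERSION


def marker_labels(mocap: pd.DataFrame) -> list[str]:
    """Marker labels that have a full ``.Pos[XYZ]`` triplet of columns."""
    cols = set(mocap.columns)
    labels = []
    for col in mocap.columns:
        m = re.fullmatch(r"(.+)\.PosX", str(col))
        if m and {f"{m.group(1)}.PosY", f"{m.group(1)}.PosZ"} <= cols:
            labels.append(m.group(1))
    return labels


@dataclass
class MissingMask:
    """Per-marker boolean series over frames (True = missing).

    All three coordinates of a marker share one mask.
    """

    mask: pd.DataFrame  # columns = marker labels, bool

    def __len__(self):
        return len(self.mask)

    @property
    def labels(self):
        return list(self.mask.columns)

    def any(self) -> bool:
        return bool(self.mask.to_numpy().any())

    def summary(self) -> pd.Series:
        """Fraction of frames missing per marker."""
        return self.mask.mean()


def detect_missing(
    mocap: pd.DataFrame, dflow_version: str, min_run: int = 3
) -> MissingMask:
    """Flag missing marker frames according to the recording-software dialect.

    New dialect (>= 3.16.2rc4): a frame is missing iff all three coordinates
    are (+/-)0.0.  Old dialect: the software repeats the last seen value, so a
    frame is missing iff all three coordinates exactly equal the previous
    frame's for a run of at least ``min_run`` frames; the run is flagged from
    its second frame onward (the first frame of the run is the genuine
    observation).
    """
    labels = marker_labels(mocap)
    out = {}
    signed_zero = uses_signed_zero_dialect(dflow_version)
    for label in labels:
        xyz = mocap[[f"{label}.Pos{ax}" for ax in "XYZ"]].to_numpy(dtype=float)
        if signed_zero:
            miss = np.all(xyz == 0.0, axis=1)
        else:
            n = len(xyz)
            miss = np.zeros(n, dtype=bool)
            if n > 1:
                same = np.all(xyz[1:] == xyz[:-1], axis=1)
                # run-length encode the "identical to previous frame" flags
                i = 0
                while i < n - 1:
                    if same[i]:
                        j = i
                        while j < n - 1 and same[j]:
                            j += 1
                        run = j - i  # frames i+1 .. j repeat frame i
                        if run + 1 >= min_run:
                            miss[i + 1 : j + 1] = True
                        i = j
                    else:
                        i += 1
        out[label] = miss
    return MissingMask(pd.DataFrame(out, index=mocap.index))


def interpolate_missing(
    mocap: pd.DataFrame, mask: MissingMask, method: str = "linear"
) -> pd.DataFrame:
    """Replace masked marker samples by interpolated estimates.

    ``method`` is one of ``linear`` (straight line between the bracketing
    valid samples), ``spline`` (cubic), or ``hold`` (last valid value).
    Unmasked samples are left bit-identical; leading/trailing gaps are filled
    with the nearest valid value.
    """
    if method not in ("linear", "spline", "hold"):
        raise ValueError(f"unknown interpolation method {method!r}")
    out = mocap.copy()
    for label in mask.labels:
        m = mask.mask[label].to_numpy()
        if not m.any():
            continue
        if m.all():
            raise IntegrityError(f"marker {label} is missing for the entire trial")
        for ax in "XYZ":
            col = f"{label}.Pos{ax}"
            series = out[col].copy()
            series[m] = np.nan
            if method == "hold":
                series = series.ffill().bfill()
            elif method == "spline":
                series = series.interpolate(method="spline", order=3,
                                            limit_direction="both")
                series = series.ffill().bfill()
            else:
                series = series.interpolate(method="linear", limit_direction="both")
            out[col] = series
    return out


@dataclass
class CleanTrial:
    """Merged, uniformly sampled trial table plus events and metadata.

    ``data`` is indexed by time (s) at one constant rate and holds marker
    coordinates (m), plate loads (N, N m), centers of pressure (m), and the
    two belt speeds (m/s).
    """

    data: pd.DataFrame
    events: EventTimeline
    meta: MetaData | None = None
    missing_report: pd.Series | None = None

    @property
    def time(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def rate(self) -> float:
        dt = np.diff(self.time)
        return 1.0 / float(np.median(dt))

    def event_time(self, name: str) -> float:
        return self.events.by_name(name).time

    def save(self, path: str | os.PathLike, key: str = "clean") -> None:
        self.data.to_hdf(path, key=key, mode="w")
        ev = pd.DataFrame(
            [(e.letter, e.name, e.time) for e in self.events],
            columns=["letter", "name", "time"],
        )
        ev.to_hdf(path, key=f"{key}_events", mode="a")

    @classmethod
    def load(cls, path: str | os.PathLike, key: str = "clean") -> "CleanTrial":
        data = pd.read_hdf(path, key=key)
        ev = pd.read_hdf(path, key=f"{key}_events")
        events = EventTimeline(
            Event(r.letter, r.name, float(r.time)) for r in ev.itertuples()
        )
        return cls(data=data, events=events)


def merge_streams(
    mocap: pd.DataFrame,
    record: pd.DataFrame,
    events: EventTimeline | None = None,
    meta: MetaData | None = None,
    missing_report: pd.Series | None = None,
) -> CleanTrial:
    """Merge the mocap and record streams at the maximum common constant rate.

    The mocap stream defines its uniform grid through the frame counter; the
    record stream's columns are linearly interpolated onto the slower of the
    two rates over the overlapping time span.
    """
    t_mocap = infer_sample_times(mocap)
    t_record = record["Time"].to_numpy(dtype=float)
    mocap_rate = 1.0 / float(np.median(np.diff(t_mocap)))
    record_rate = 1.0 / float(np.median(np.diff(t_record)))
    rate = min(mocap_rate, record_rate)

    t0 = max(t_mocap[0], t_record[0])
    t1 = min(t_mocap[-1], t_record[-1])
    if t1 <= t0:
        raise IntegrityError("mocap and record streams do not overlap in time")
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate

    out = {}
    for col in mocap.columns:
        if col in ("TimeStamp", "FrameNumber"):
            continue
        out[col] = np.interp(grid, t_mocap, mocap[col].to_numpy(dtype=float))
    for col in record.columns:
        if col == "Time":
            continue
        out[col] = np.interp(grid, t_record, record[col].to_numpy(dtype=float))
    df = pd.DataFrame(out, index=pd.Index(grid, name="Time"))
    events = EventTimeline(events or [])
    return CleanTrial(data=df, events=events, meta=meta, missing_report=missing_report)


def extract_event_segment(trial: CleanTrial, event_name: str) -> CleanTrial:
    """Rows from the named event up to the next event (or end of data).

    The returned segment's time index and event times are re-based to start
    at zero.
    """
    names = [e.name for e in trial.events]
    if event_name not in names:
        raise KeyError(f"unknown event {event_name!r}; available: {names}")
    i = names.index(event_name)
    t_start = trial.events[i].time
    t_end = trial.events[i + 1].time if i + 1 < len(trial.events) else np.inf
    t = trial.time
    sel = (t >= t_start - 1e-9) & (t < t_end - 1e-9)
    data = trial.data.loc[sel].copy()
    new_t0 = float(data.index[0]) if len(data) else t_start
    data.index = pd.Index(data.index.to_numpy() - new_t0, name="Time")
    events = EventTimeline(
        Event(e.letter, e.name, e.time - new_t0)
        for e in trial.events
        if t_start - 1e-9 <= e.time < t_end - 1e-9
    )
    return CleanTrial(data=data, events=events, meta=trial.meta,
                      missing_report=trial.missing_report)


def measured_mass(
    trial: CleanTrial, window: float = 1.0, event_name: str = "Calibration Pose"
) -> tuple[float, float]:
    """Body mass from total vertical GRF just after the calibration pose.

    Returns ``(mass, sd)`` in kg where mass is the mean over the window of
    ``(FP1.ForY + FP2.ForY) / g`` and sd the standard deviation of the
    per-sample mass.
    """
    for col in ("FP1.ForY", "FP2.ForY"):
        if col not in trial.data.columns:
            raise KeyError(f"vertical force column {col!r} missing")
    t0 = trial.event_time(event_name)
    t = trial.time
    sel = (t >= t0 - 1e-9) & (t < t0 + window - 1e-9)
    if not sel.any():
        raise IntegrityError(f"no samples in {window} s window after {event_name!r}")
    fy = (trial.data.loc[sel, "FP1.ForY"] + trial.data.loc[sel, "FP2.ForY"]).to_numpy()
    m = fy / GRAVITY
    return float(np.mean(m)), float(np.std(m, ddof=1)) if len(m) > 1 else 0.0


# ---------------------------------------------------------------------------
# belt-inertia load compensation
# ---------------------------------------------------------------------------

LOAD_COLUMNS = tuple(
    f"FP{plate}.{kind}{ax}" for plate in (1, 2) for kind in ("For", "Mom")
    for ax in "XYZ"
)

#: Which belt drives which plate: plate 1 is under the left foot.
PLATE_BELT = {1: "LeftBeltSpeed", 2: "RightBeltSpeed"}


@dataclass
class CompensationModel:
    """Linear map from belt acceleration to load error, per load channel.

    Fitted on an unloaded (no-subject) trial; applied subtractively.
    """

    coefficients: dict = field(default_factory=dict)  # column -> (slope, intercept)
    cutoff: float = 6.0

    def predict(self, column: str, accel: np.ndarray) -> np.ndarray:
        slope, intercept = self.coefficients.get(column, (0.0, 0.0))
        return slope * accel + intercept


def belt_acceleration(trial: CleanTrial, column: str, cutoff: float = 6.0) -> np.ndarray:
    """Low-pass-filtered central-difference acceleration of a belt speed."""
    v = trial.data[column].to_numpy(dtype=float)
    rate = trial.rate
    b, a = butter(2, cutoff / (rate / 2.0), "lowpass")
    v_f = filtfilt(b, a, v)
    return np.gradient(v_f, 1.0 / rate)


def fit_compensation(unloaded: CleanTrial, cutoff: float = 6.0) -> CompensationModel:
    """Fit per-channel OLS of load on belt acceleration from an unloaded trial."""
    model = CompensationModel(cutoff=cutoff)
    accels = {p: belt_acceleration(unloaded, c, cutoff) for p, c in PLATE_BELT.items()
              if c in unloaded.data.columns}
    if not accels:
        raise IntegrityError("unloaded trial has no belt speed columns")
    for col in LOAD_COLUMNS:
        if col not in unloaded.data.columns:
            continue
        plate = int(col[2])
        accel = accels[plate]
        load = unloaded.data[col].to_numpy(dtype=float)
        var = float(np.var(accel))
        if var < 1e-10:
            if float(np.std(load)) < 1e-12 or np.allclose(load, load.mean()):
                model.coefficients[col] = (0.0, float(np.mean(load)))
                continue
            raise IntegrityError(
                f"belt acceleration variance {var:.2e} too small to identify "
                f"a compensation slope for {col}"
            )
        slope = float(np.cov(accel, load, ddof=0)[0, 1] / var)
        intercept = float(np.mean(load) - slope * np.mean(accel))
        model.coefficients[col] = (slope, intercept)
    return model


def apply_compensation(trial: CleanTrial, model: CompensationModel) -> CleanTrial:
    """Subtract predicted inertia-induced load errors; re-derive CoP columns.

    Centers of pressure are recomputed from the compensated loads with the
    shared treadmill-surface origin convention (X right, Y up, Z backward)::

        CoP_x = -M_z / F_y      CoP_z = M_x / F_y      CoP_y = 0

    Samples with |F_y| below 20 N get NaN CoP.
    """
    data = trial.data.copy()
    for plate, belt_col in PLATE_BELT.items():
        if belt_col not in data.columns:
            continue
        accel = belt_acceleration(trial, belt_col, model.cutoff)
        for col in LOAD_COLUMNS:
            if col in data.columns and int(col[2]) == plate and col in model.coefficients:
                data[col] = data[col].to_numpy(dtype=float) - model.predict(col, accel)
    for plate in (1, 2):
        fy_col, mx_col, mz_col = (f"FP{plate}.ForY", f"FP{plate}.MomX", f"FP{plate}.MomZ")
        if not {fy_col, mx_col, mz_col} <= set(data.columns):
            continue
        fy = data[fy_col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cop_x = -data[mz_col].to_numpy(dtype=float) / fy
            cop_z = data[mx_col].to_numpy(dtype=float) / fy
        invalid = np.abs(fy) < COP_FORCE_THRESHOLD
        cop_x[invalid] = np.nan
        cop_z[invalid] = np.nan
        if f"FP{plate}.CopX" in data.columns:
            data[f"FP{plate}.CopX"] = cop_x
            data[f"FP{plate}.CopY"] = 0.0
            data[f"FP{plate}.CopZ"] = cop_z
    return CleanTrial(data=data, events=trial.events, meta=trial.meta,
                      missing_report=trial.missing_report)


def rezero_forces(trial: CleanTrial, window: float = 1.0,
                  event_name: str = "Force Plate Zeroing") -> CleanTrial:
    """Subtract the mean load over the zeroing window from every load channel.

    Off by default in :func:`clean_trial` since the hardware zeroes at the
    start of each trial.
    """
    t0 = trial.event_time(event_name)
    t = trial.time
    sel = (t >= t0 - 1e-9) & (t < t0 + window - 1e-9)
    data = trial.data.copy()
    for col in LOAD_COLUMNS:
        if col in data.columns:
            data[col] = data[col] - float(data.loc[sel, col].mean())
    return CleanTrial(data=data, events=trial.events, meta=trial.meta,
                      missing_report=trial.missing_report)


def clean_trial(
    bundle,
    interpolation: str | None = "linear",
    rezero: bool = False,
    compensation: CompensationModel | None = None,
) -> CleanTrial:
    """Run the full cleaning pipeline on a parsed trial bundle.

    Steps: detect missing markers per the software dialect, interpolate them,
    merge the two streams onto one constant-rate grid, optionally re-zero
    forces over the zeroing event window and apply a belt-inertia
    compensation model.
    """
    mocap = bundle.mocap
    report = None
    if interpolation is not None and bundle.meta is not None:
        version = bundle.meta.dflow_version or "3.16.2rc4"
        mask = detect_missing(mocap, version)
        report = mask.summary()
        if mask.any():
            mocap = interpolate_missing(mocap, mask, interpolation)
    trial = merge_streams(mocap, bundle.record, events=bundle.events,
                          meta=bundle.meta, missing_report=report)
    if rezero:
        trial = rezero_forces(trial)
    if compensation is not None:
        trial = apply_compensation(trial, compensation)
    return trial
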