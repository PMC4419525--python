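"""Gait event detection, cycle splitting and stride statistics.

Heel strikes and toe offs are detected as threshold crossings of each
plate's vertical ground reaction force (plate 1 = left foot, plate 2 =
right).  Cycles run between consecutive heel strikes of one side and are
time-normalized onto a fixed percent-of-cycle grid, after which per-cycle
stride statistics (average belt speed, stride frequency, length and width)
and ensemble summaries can be computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitkit.cleaning import CleanTrial

__all__ = [
    "GaitLandmarks",
    "GaitCycleSet",
    "EnsembleStats",
    "detect_grf_landmarks",
    "split_cycles",
    "stride_statistics",
    "ensemble_stats",
]

SIDE_FORCE_COLUMNS = {"left": "FP1.ForY", "right": "FP2.ForY"}
SIDE_BELT_COLUMNS = {"left": "LeftBeltSpeed", "right": "RightBeltSpeed"}
SIDE_HEEL = {"left": "LHEE", "right": "RHEE"}


@dataclass
class GaitLandmarks:
    """Heel-strike and toe-off times per side, from GRF threshold crossings."""

    heel_strikes: dict = field(default_factory=dict)  # side -> np.ndarray of s
    toe_offs: dict = field(default_factory=dict)
    threshold: float = 20.0


def _threshold_crossings(
    t: np.ndarray, f: np.ndarray, threshold: float, rising: bool, refractory: float
) -> np.ndarray:
    """Sub-sample crossing times with a refractory debounce.

    The crossing instant is linearly interpolated between the bracketing
    samples; crossings closer than ``refractory`` to the previously accepted
    one of the same kind are discarded as chatter.
    """
    above = f >= threshold
    if rising:
        idx = np.flatnonzero(~above[:-1] & above[1:])
    else:
        idx = np.flatnonzero(above[:-1] & ~above[1:])
    times = []
    last = -np.inf
    for i in idx:
        f0, f1 = f[i], f[i + 1]
        frac = (threshold - f0) / (f1 - f0) if f1 != f0 else 0.0
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return np.asarray(times)


def detect_grf_landmarks(
    trial: CleanTrial, threshold: float = 20.0, refractory: float = 0.2
) -> GaitLandmarks:
    """Detect heel strikes (upward crossings) and toe offs (downward).

    ``threshold`` is in Newtons (20 N by default, well above plate noise and
    well below body weight).
    """
    landmarks = GaitLandmarks(threshold=threshold)
    t = trial.time
    for side, col in SIDE_FORCE_COLUMNS.items():
        if col not in trial.data.columns:
            raise KeyError(f"vertical force column {col!r} missing for side {side!r}")
        f = trial.data[col].to_numpy(dtype=float)
        hs = _threshold_crossings(t, f, threshold, True, refractory)
        to = _threshold_crossings(t, f, threshold, False, refractory)
        if len(hs) == 0 and len(to) == 0:
            warnings.warn(f"no {threshold} N crossings found on side {side!r}")
        landmarks.heel_strikes[side] = hs
        landmarks.toe_offs[side] = to
    return landmarks


@dataclass
class GaitCycleSet:
    """Time-normalized gait cycles split at one side's heel strikes.

    Every cycle is a DataFrame with ``samples_per_cycle`` rows indexed by
    percent of gait cycle (0-100), sharing the source trial's columns.
    ``durations`` holds each retained cycle's true duration in seconds.
    """

    cycles: list = field(default_factory=list)
    durations: np.ndarray = field(default_factory=lambda: np.array([]))
    start_times: np.ndarray = field(default_factory=lambda: np.array([]))
    side: str = "right"
    dropped: list = field(default_factory=list)  # (start_time, duration) of outliers

    def __len__(self):
        return len(self.cycles)

    @property
    def columns(self):
        return list(self.cycles[0].columns) if self.cycles else []

    def save(self, path, key: str = "cycles") -> None:
        stacked = pd.concat(self.cycles, keys=range(len(self.cycles)),
                            names=["cycle", "percent"])
        stacked.to_hdf(path, key=key, mode="a")
        meta = pd.DataFrame({"duration": self.durations, "start": self.start_times})
        meta.to_hdf(path, key=f"{key}_meta", mode="a")


def split_cycles(
    trial: CleanTrial,
    landmarks: GaitLandmarks,
    side: str = "right",
    samples_per_cycle: int = 101,
    duration_tolerance: float = 0.5,
) -> GaitCycleSet:
    """Split a trial into time-normalized gait cycles.

    Each interval between consecutive heel strikes of ``side`` is resampled
    by linear interpolation onto a 0-100% grid with ``samples_per_cycle``
    points.  Cycles whose duration deviates more than ``duration_tolerance``
    (fractional) from the median duration are dropped and reported in
    ``dropped``.
    """
    hs = np.asarray(landmarks.heel_strikes.get(side, ()))
    if len(hs) < 2:
        raise ValueError(f"need at least 2 heel strikes on side {side!r}, got {len(hs)}")
    t = trial.time
    durations_all = np.diff(hs)
    median = float(np.median(durations_all))
    grid_pct = np.linspace(0.0, 100.0, samples_per_cycle)
    values = trial.data.to_numpy(dtype=float)
    cycles, durations, starts, dropped = [], [], [], []
    for t0, dur in zip(hs[:-1], durations_all):
        if abs(dur - median) > duration_tolerance * median:
            dropped.append((float(t0), float(dur)))
            continue
        tq = t0 + grid_pct / 100.0 * dur
        resampled = np.empty((samples_per_cycle, values.shape[1]))
        for j in range(values.shape[1]):
            resampled[:, j] = np.interp(tq, t, values[:, j])
        cycles.append(pd.DataFrame(resampled, columns=trial.data.columns,
                                   index=pd.Index(grid_pct, name="Percent")))
        durations.append(float(dur))
        starts.append(float(t0))
    return GaitCycleSet(
        cycles=cycles, durations=np.asarray(durations),
        start_times=np.asarray(starts), side=side, dropped=dropped,
    )


def stride_statistics(
    cycles: GaitCycleSet, trial: CleanTrial, landmarks: GaitLandmarks | None = None
) -> pd.DataFrame:
    """Per-cycle stride statistics.

    For each retained cycle:

    * ``Average Belt Speed`` (m/s): mean of the splitting side's belt speed.
    * ``Stride Frequency`` (Hz): 1 / cycle duration.
    * ``Stride Length`` (m): integral of belt speed over the cycle plus the
      change of the heel's forward position (forward = -Z) from cycle start
      to end, so a heel that lands short of where it started shortens the
      stride.
    * ``Stride Width`` (m): absolute lateral (X) distance between the two
      heel markers, each sampled at its own side's heel strike within the
      cycle.
    """
    side = cycles.side
    other = "left" if side == "right" else "right"
    belt_col = SIDE_BELT_COLUMNS[side]
    heel = SIDE_HEEL[side]
    other_heel = SIDE_HEEL[other]
    for col in (belt_col, f"{heel}.PosZ", f"{heel}.PosX", f"{other_heel}.PosX"):
        if col not in trial.data.columns:
            raise KeyError(f"column {col!r} required for stride statistics")
    t = trial.time
    own_x = trial.data[f"{heel}.PosX"].to_numpy(dtype=float)
    other_x = trial.data[f"{other_heel}.PosX"].to_numpy(dtype=float)
    other_hs = (np.asarray(landmarks.heel_strikes.get(other, ()))
                if landmarks is not None else np.array([]))

    rows = []
    for cyc, dur, t0 in zip(cycles.cycles, cycles.durations, cycles.start_times):
        pct = cyc.index.to_numpy() / 100.0
        belt = cyc[belt_col].to_numpy(dtype=float)
        avg_speed = float(np.trapezoid(belt, pct * dur) / dur)
        freq = 1.0 / dur
        forward = -cyc[f"{heel}.PosZ"].to_numpy(dtype=float)
        length = float(np.trapezoid(belt, pct * dur) + (forward[0] - forward[-1]))
        x_own = float(np.interp(t0, t, own_x))
        in_cycle = other_hs[(other_hs >= t0) & (other_hs < t0 + dur)]
        if len(in_cycle):
            x_other = float(np.interp(in_cycle[0], t, other_x))
        else:
            # no contralateral strike recorded in this cycle; sample mid-cycle
            x_other = float(np.interp(t0 + dur / 2.0, t, other_x))
        rows.append({
            "Average Belt Speed": avg_speed,
            "Stride Frequency": freq,
            "Stride Length": length,
            "Stride Width": abs(x_own - x_other),
        })
    return pd.DataFrame(rows)


@dataclass
class EnsembleStats:
    """Across-cycle summaries.

    ``mean``/``sd`` are pointwise curves over the normalized grid (``sd`` is
    None for a single cycle); ``five_number`` summarizes scalar stride
    statistics with Tukey-hinge quartiles.
    """

    mean: pd.DataFrame | None = None
    sd: pd.DataFrame | None = None
    five_number: pd.DataFrame | None = None
    n: int = 0


def _five_number(values: np.ndarray) -> dict:
    return {
        "min": float(np.min(values)),
        "q1": float(np.percentile(values, 25, method="midpoint")),
        "median": float(np.median(values)),
        "q3": float(np.percentile(values, 75, method="midpoint")),
        "max": float(np.max(values)),
    }


def ensemble_stats(data: GaitCycleSet | pd.DataFrame) -> EnsembleStats:
    """Pointwise mean/SD curves over cycles, or five-number summaries.

    Pass a :class:`GaitCycleSet` for ensemble curves or a stride-statistics
    DataFrame for scalar summaries.  Quartiles use the midpoint (Tukey
    hinge) convention.
    """
    if isinstance(data, pd.DataFrame):
        summary = pd.DataFrame({c: _five_number(data[c].to_numpy()) for c in data})
        return EnsembleStats(five_number=summary, n=len(data))
    if len(data) == 0:
        raise ValueError("no cycles to summarize")
    stack = np.stack([c.to_numpy(dtype=float) for c in data.cycles])
    index = data.cycles[0].index
    columns = data.cycles[0].columns
    mean = pd.DataFrame(stack.mean(axis=0), index=index, columns=columns)
    if len(data) > 1:
        sd = pd.DataFrame(stack.std(axis=0, ddof=1), index=index, columns=columns)
    else:
        warnings.warn("single cycle: SD curve undefined")
        sd = None
    return EnsembleStats(mean=mean, sd=sd, n=len(data))


def plot_gait_cycles(
    cycles: GaitCycleSet, column: str, n_sigma: float = 3.0, ax=None
):
    """Mean +/- n-sigma band of one column across cycles (matplotlib axes)."""
    import matplotlib.pyplot as plt

    stats = ensemble_stats(cycles)
    if ax is None:
        _, ax = plt.subplots()
    pct = stats.mean.index.to_numpy()
    mu = stats.mean[column].to_numpy()
    ax.plot(pct, mu, label=column)
    if stats.sd is not None:
        sigma = stats.sd[column].to_numpy()
        ax.fill_between(pct, mu - n_sigma * sigma, mu + n_sigma * sigma, alpha=0.3)
    ax.set_xlabel("Gait cycle (%)")
    ax.set_ylabel(column)
    return ax
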