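"""Pseudo-random treadmill perturbation signal synthesis.

Longitudinal belt-speed signals are built by the same block chain the
original control setup used: discrete Gaussian white-noise acceleration
sampled at the control rate, saturated at the maximum belt acceleration,
integrated to speed, high-pass filtered with a causal second-order
Butterworth to remove drift, shifted to the nominal mean speed and clipped to
the physical speed range.  Lateral platform-displacement signals integrate
the noise twice and saturate at the hardware's travel range.

The white-noise standard deviation is calibrated per mean speed so that the
resulting signal standard deviations match the study values (0.06, 0.12 and
0.21 m/s at 0.8, 1.2 and 1.6 m/s).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, welch

__all__ = [
    "PerturbationParams",
    "BeltSignal",
    "generate_belt_signal",
    "calibrate",
    "default_params",
    "generate_lateral_signal",
    "spectral_density",
    "write_signal_file",
    "read_signal_file",
    "CALIBRATED_NOISE_SD",
    "STUDY_TARGET_SD",
]

#: Signal SDs the study aimed for at each nominal belt speed (m/s -> m/s).
STUDY_TARGET_SD = {0.8: 0.06, 1.2: 0.12, 1.6: 0.21}

#: White-noise acceleration SD (m/s^2) per nominal speed, produced once by
#: running :func:`calibrate` against STUDY_TARGET_SD and frozen here.
CALIBRATED_NOISE_SD = {0.8: 0.800781, 1.2: 1.601562, 1.6: 2.796875}


@dataclass(frozen=True)
class PerturbationParams:
    """Generation parameters for a pseudo-random belt-speed signal."""

    mean_speed: float = 1.2        # m/s
    noise_sd: float = 2.0          # m/s^2, pre-saturation white-noise SD
    accel_limit: float = 15.0      # m/s^2, saturation block
    speed_bounds: tuple = (0.0, 3.6)  # m/s
    highpass_cutoff: float = 0.1   # Hz
    rate: float = 100.0            # Hz
    duration: float = 480.0        # s
    seed: int = 0

    def validate(self) -> None:
        if self.accel_limit <= 0:
            raise ValueError("accel_limit must be positive")
        lo, hi = self.speed_bounds
        if not lo < hi:
            raise ValueError("speed_bounds must be ordered")
        if not lo <= self.mean_speed <= hi:
            raise ValueError("mean_speed outside speed_bounds")
        if self.highpass_cutoff >= self.rate / 2.0:
            raise ValueError("high-pass cutoff at or above Nyquist")
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")


@dataclass
class BeltSignal:
    """A commanded belt-speed (or lateral displacement) time series."""

    time: np.ndarray
    speed: np.ndarray
    params: PerturbationParams | None = None

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def sd(self) -> float:
        return float(np.std(self.speed))


def _white_noise(n: int, sd: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def prefilter_acceleration(params: PerturbationParams) -> np.ndarray:
    """The saturated white-noise acceleration the integrator consumes."""
    n = int(round(params.duration * params.rate))
    accel = _white_noise(n, params.noise_sd, params.seed)
    np.clip(accel, -params.accel_limit, params.accel_limit, out=accel)
    return accel


def generate_belt_signal(params: PerturbationParams) -> BeltSignal:
    """Generate a longitudinal belt-speed perturbation signal.

    Deterministic given the seed.  Clamp order follows the control diagram:
    acceleration saturation before integration, speed clipping last.
    """
    params.validate()
    n = int(round(params.duration * params.rate))
    dt = 1.0 / params.rate
    accel = prefilter_acceleration(params)
    speed = np.cumsum(accel) * dt
    if params.noise_sd > 0:
        b, a = butter(2, params.highpass_cutoff / (params.rate / 2.0), "highpass")
        speed = lfilter(b, a, speed)
    speed = speed + params.mean_speed
    np.clip(speed, *params.speed_bounds, out=speed)
    time = np.arange(n) * dt
    return BeltSignal(time=time, speed=speed, params=params)


def _mean_sd(params: PerturbationParams, n_seeds: int, seed0: int) -> float:
    sds = [
        generate_belt_signal(replace(params, seed=seed0 + i)).sd()
        for i in range(n_seeds)
    ]
    return float(np.mean(sds))


def calibrate(
    mean_speed: float,
    target_sd: float,
    n_seeds: int = 10,
    tolerance: float = 0.02,
    max_iter: int = 50,
    seed0: int = 0,
    **kwargs,
) -> PerturbationParams:
    """Bisect the white-noise SD until the signal SD matches the target.

    The high-pass cutoff stays fixed; only the noise SD is searched.  The
    match criterion is the mean over ``n_seeds`` realizations of the signal
    sample SD landing within ``tolerance`` (relative) of ``target_sd``.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    base = PerturbationParams(mean_speed=mean_speed, noise_sd=1.0, **kwargs)
    base.validate()
    lo, hi = 0.0, 1.0
    # grow the bracket until the target is straddled
    for _ in range(30):
        if _mean_sd(replace(base, noise_sd=hi), n_seeds, seed0) >= target_sd:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError(
            f"target SD {target_sd} unreachable under the clamps (bracket hi={hi})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        got = _mean_sd(replace(base, noise_sd=mid), n_seeds, seed0)
        if abs(got - target_sd) <= tolerance * target_sd:
            return replace(base, noise_sd=mid)
        if got < target_sd:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge in {max_iter} iterations "
        f"(bracket [{lo}, {hi}], target {target_sd})"
    )


def default_params(mean_speed: float, **kwargs) -> PerturbationParams:
    """Shipped calibrated parameters for one of the three study speeds."""
    if mean_speed not in CALIBRATED_NOISE_SD:
        raise KeyError(
            f"no shipped calibration for {mean_speed} m/s; "
            f"available: {sorted(CALIBRATED_NOISE_SD)} (use calibrate())"
        )
    return PerturbationParams(
        mean_speed=mean_speed, noise_sd=CALIBRATED_NOISE_SD[mean_speed], **kwargs
    )


def generate_lateral_signal(
    amplitude_limit: float = 0.05,
    rate: float = 100.0,
    duration: float = 240.0,
    seed: int = 0,
    noise_sd: float = 0.1,
    highpass_cutoff: float = 0.1,
) -> BeltSignal:
    """Pseudo-random lateral platform displacement (m).

    White noise is twice integrated to displacement, high-pass filtered to
    remove drift, and saturated at the hardware's lateral travel range
    (+/- 5 cm by default).
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive")
    if highpass_cutoff >= rate / 2.0:
        raise ValueError("high-pass cutoff at or above Nyquist")
    n = int(round(duration * rate))
    dt = 1.0 / rate
    noise = _white_noise(n, noise_sd, seed)
    disp = np.cumsum(np.cumsum(noise) * dt) * dt
    if noise_sd > 0:
        b, a = butter(2, highpass_cutoff / (rate / 2.0), "highpass")
        disp = lfilter(b, a, disp)
    np.clip(disp, -amplitude_limit, amplitude_limit, out=disp)
    return BeltSignal(time=np.arange(n) * dt, speed=disp, params=None)


def spectral_density(
    signal: BeltSignal | np.ndarray,
    window: float = 20.0,
    rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged power spectral density with Hamming-tapered segments.

    Segments of ``window`` seconds overlap 50%; the density is normalized so
    its integral over frequency approximates the signal variance.
    """
    if isinstance(signal, BeltSignal):
        x = signal.speed
        rate = signal.rate
    else:
        x = np.asarray(signal, dtype=float)
        if rate is None:
            raise ValueError("rate required for a bare array")
    nper = int(round(window * rate))
    if nper > len(x):
        raise ValueError(f"window {window} s longer than signal ({len(x) / rate} s)")
    freq, power = welch(
        x, fs=rate, window="hamming", nperseg=nper, noverlap=nper // 2,
        detrend="constant", scaling="density",
    )
    return freq, power


def write_signal_file(signal: BeltSignal, path: str | os.PathLike) -> None:
    """Write a comma-delimited time,speed file at six decimals."""
    with open(path, "w", newline="\n") as fh:
        fh.write("Time,Speed\n")
        for t, v in zip(signal.time, signal.speed):
            fh.write(f"{t:.6f},{v:.6f}\n")


def read_signal_file(path: str | os.PathLike) -> BeltSignal:
    df = pd.read_csv(path)
    return BeltSignal(
        time=df.iloc[:, 0].to_numpy(dtype=float),
        speed=df.iloc[:, 1].to_numpy(dtype=float),
    )
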