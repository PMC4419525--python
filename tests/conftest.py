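import numpy as np
import pandas as pd
import pytest

from gaitkit import cleaning, trial_io
from gaitkit.perturbation import default_params
from gaitkit.synthetic import SynthConfig, emit, simulate_gait


def random_bundle(rng: np.random.Generator, n: int = 12) -> trial_io.TrialBundle:
    """A small random but internally consistent trial bundle."""
    t = np.arange(n) * 0.01
    mocap = pd.DataFrame({
        "TimeStamp": np.round(t + rng.uniform(0, 2e-3, n), 6),
        "FrameNumber": np.arange(1, n + 1),
        "LHEE.PosX": np.round(rng.normal(0, 1, n), 6),
        "LHEE.PosY": np.round(rng.normal(1, 0.2, n), 6),
        "LHEE.PosZ": np.round(rng.normal(0, 1, n), 6),
        "FP1.ForY": np.round(rng.uniform(0, 800, n), 6),
        "Channel1.Anlg": np.round(rng.normal(0, 5, n), 6),
    })
    record = pd.DataFrame({
        "Time": np.round(t, 6),
        "RightBeltSpeed": np.round(rng.uniform(0, 2, n), 6),
        "LeftBeltSpeed": np.round(rng.uniform(0, 2, n), 6),
    })
    k = int(rng.integers(0, 4))
    letters = ["A", "B", "C", "D", "E", "F"][:k]
    times = np.sort(rng.choice(t, size=k, replace=False)) if k else []
    events = trial_io.EventTimeline(
        trial_io.Event(l, trial_io.DEFAULT_EVENTS[l], float(tt))
        for l, tt in zip(letters, times)
    )
    meta = trial_io.MetaData(
        study={"id": 1, "name": "t", "description": "d"},
        subject={"id": 7, "age": 25, "gender": "female", "mass": 61.0,
                 "height": 1.66},
        trial={"id": int(rng.integers(1, 999)), "subject-id": 7,
               "nominal-speed": 1.2, "marker-set": "lower",
               "dflow-version": "3.16.2rc4",
               "events": dict(trial_io.DEFAULT_EVENTS), "files": {}},
    )
    return trial_io.TrialBundle(meta=meta, mocap=mocap, record=record, events=events)


@pytest.fixture(scope="session")
def unperturbed_run(tmp_path_factory):
    """Noise-free unperturbed trial emitted to disk and read back."""
    cfg = SynthConfig(
        phases={"zeroing": 2, "calibration": 2, "first_normal": 45,
                "perturbation": 80, "second_normal": 2, "unloaded": 2},
        perturbation=None, seed=11,
    )
    bundle, truth = simulate_gait(cfg)
    d = tmp_path_factory.mktemp("synth_u")
    emit(bundle, truth, d)
    read = trial_io.read_trial(d / f"T{cfg.trial_id:03d}")
    trial = cleaning.clean_trial(read)
    return {"config": cfg, "bundle": bundle, "truth": truth, "trial": trial,
            "dir": d / f"T{cfg.trial_id:03d}"}


@pytest.fixture(scope="session")
def perturbed_run():
    """Noise-free perturbed trial (in memory; same cycle-count window)."""
    cfg = SynthConfig(
        phases={"zeroing": 2, "calibration": 2, "first_normal": 5,
                "perturbation": 80, "second_normal": 2, "unloaded": 2},
        perturbation=default_params(1.2), seed=11,
    )
    bundle, truth = simulate_gait(cfg)
    trial = cleaning.clean_trial(bundle)
    return {"config": cfg, "bundle": bundle, "truth": truth, "trial": trial}
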