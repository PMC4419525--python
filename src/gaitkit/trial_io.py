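"""Reading and writing the three-file treadmill trial format.

A trial lives in a directory ``T<nnn>/`` holding three files:

``mocap-<nnn>.txt``
    Tab-separated stream from the motion-capture acquisition software: a
    ``TimeStamp`` column (s), a ``FrameNumber`` column (monotonic positive
    integers), marker coordinates in meters under ``<LABEL>.Pos[XYZ]``
    headers, force-plate loads under ``FP{1,2}.For[XYZ]`` (N) /
    ``FP{1,2}.Mom[XYZ]`` (N m) / ``FP{1,2}.Cop[XYZ]`` (m), and analog
    voltages under ``Channel<k>.Anlg``.  All numeric cells are fixed-point
    with six decimals.

``record-<nnn>.txt``
    Tab-separated ``Time`` / ``RightBeltSpeed`` / ``LeftBeltSpeed`` stream
    with ``#``-commented lines marking protocol events (letters A-F)
    inserted between data rows.

``meta-<nnn>.yml``
    YAML metadata with three top-level headings: ``study``, ``subject`` and
    ``trial``.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MetaData",
    "Event",
    "EventTimeline",
    "TrialBundle",
    "FormatError",
    "IntegrityError",
    "MetaValidationError",
    "parse_meta",
    "parse_mocap",
    "parse_record",
    "infer_sample_times",
    "write_trial",
]

#: Default letter -> name map used when a meta file does not provide one.
DEFAULT_EVENTS = {
    "A": "Force Plate Zeroing",
    "B": "Calibration Pose",
    "C": "First Normal Walking",
    "D": "Longitudinal Perturbation",
    "E": "Second Normal Walking",
    "F": "Unloaded End",
}

MARKER_SETS = ("full", "lower", "NA")


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class IntegrityError(ValueError):
    """A file parses but violates an internal consistency rule."""


class MetaValidationError(ValueError):
    """A meta file is missing required keys or has wrongly typed values."""


@dataclass
class MetaData:
    """Validated contents of a ``meta-<nnn>.yml`` file.

    The three documented headings are kept as plain dictionaries so that
    unrecognized keys pass through untouched; convenience accessors pull out
    the fields the rest of the toolkit needs.
    """

    study: dict = field(default_factory=dict)
    subject: dict = field(default_factory=dict)
    trial: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)

    @property
    def trial_id(self) -> int:
        return int(self.trial["id"])

    @property
    def events(self) -> dict:
        ev = self.trial.get("events")
        return dict(ev) if ev else dict(DEFAULT_EVENTS)

    @property
    def marker_map(self) -> dict:
        return dict(self.trial.get("marker-map") or {})

    @property
    def analog_channel_map(self) -> dict:
        return dict(self.trial.get("analog-channel-map") or {})

    @property
    def dflow_version(self) -> str:
        return str(self.trial.get("dflow-version", ""))

    @property
    def nominal_speed(self) -> float:
        return float(self.trial.get("nominal-speed", 0.0))

    def to_dict(self) -> dict:
        out = {"study": self.study, "subject": self.subject, "trial": self.trial}
        out.update(self.extra)
        return out


@dataclass(frozen=True)
class Event:
    letter: str
    name: str
    time: float


class EventTimeline(list):
    """Ordered list of :class:`Event` with non-decreasing times."""

    def times(self) -> dict:
        return {e.name: e.time for e in self}

    def by_name(self, name: str) -> Event:
        for e in self:
            if e.name == name:
                return e
        raise KeyError(
            f"event {name!r} not present; available: {[e.name for e in self]}"
        )


@dataclass
class TrialBundle:
    """The three parsed per-trial streams plus validated metadata."""

    meta: MetaData
    mocap: pd.DataFrame
    record: pd.DataFrame
    events: EventTimeline


# ---------------------------------------------------------------------------
# meta files
# ---------------------------------------------------------------------------

_KNOWN_SUBJECT_TYPES = {
    "id": (int,),
    "age": (int,),
    "mass": (int, float),
    "height": (int, float),
    "gender": (str,),
}
_KNOWN_TRIAL_TYPES = {
    "id": (int,),
    "subject-id": (int,),
    "nominal-speed": (int, float),
    "stationary-platform": (bool,),
    "pitch": (bool,),
    "sway": (bool,),
    "dflow-version": (str, float),
    "cortex-version": (str, float),
    "marker-map": (dict,),
    "analog-channel-map": (dict,),
    "events": (dict,),
    "files": (dict,),
    "notes": (str,),
}


def parse_meta(path: str | os.PathLike, strict: bool = True) -> MetaData:
    """Load and validate a ``meta-<nnn>.yml`` file.

    Unrecognized top-level keys are preserved in :attr:`MetaData.extra`;
    schema violations are collected in :attr:`MetaData.violations` and, when
    ``strict``, missing ``trial.id`` / ``trial.files`` or wrongly typed known
    keys raise :class:`MetaValidationError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MetaValidationError(f"{path}: meta file is not a YAML mapping")
    meta = MetaData(
        study=dict(raw.get("study") or {}),
        subject=dict(raw.get("subject") or {}),
        trial=dict(raw.get("trial") or {}),
        extra={k: v for k, v in raw.items() if k not in ("study", "subject", "trial")},
    )
    violations = []
    if "id" not in meta.trial:
        violations.append("trial.id missing")
    if "files" not in meta.trial:
        violations.append("trial.files missing")
    for key, types in _KNOWN_TRIAL_TYPES.items():
        if key in meta.trial and meta.trial[key] is not None:
            if not isinstance(meta.trial[key], types):
                violations.append(f"trial.{key} has wrong type "
                                  f"({type(meta.trial[key]).__name__})")
    for key, types in _KNOWN_SUBJECT_TYPES.items():
        if key in meta.subject and meta.subject[key] is not None:
            if not isinstance(meta.subject[key], types):
                violations.append(f"subject.{key} has wrong type "
                                  f"({type(meta.subject[key]).__name__})")
    ev = meta.trial.get("events")
    if isinstance(ev, dict):
        for letter in ev:
            if not re.fullmatch(r"[A-Z]", str(letter)):
                violations.append(f"event key {letter!r} is not a single capital letter")
    ms = meta.trial.get("marker-set")
    if ms is not None and ms not in MARKER_SETS:
        violations.append(f"trial.marker-set {ms!r} not one of {MARKER_SETS}")
    meta.violations = violations
    if strict and violations:
        raise MetaValidationError(f"{path}: " + "; ".join(violations))
    return meta


# ---------------------------------------------------------------------------
# mocap files
# ---------------------------------------------------------------------------

def _relabel_columns(columns, meta: MetaData | None):
    if meta is None:
        return list(columns)
    marker_map = meta.marker_map
    analog_map = meta.analog_channel_map
    out = []
    for col in columns:
        if col in analog_map:
            out.append(analog_map[col])
            continue
        m = re.fullmatch(r"(.+)\.(Pos[XYZ])", col)
        if m and m.group(1) in marker_map:
            out.append(f"{marker_map[m.group(1)]}.{m.group(2)}")
        else:
            out.append(col)
    return out


def parse_mocap(path: str | os.PathLike, meta: MetaData | None = None) -> pd.DataFrame:
    """Parse a ``mocap-<nnn>.txt`` tab-separated stream.

    Columns are relabeled through ``meta.trial['marker-map']`` (marker labels,
    applied to each ``.Pos[XYZ]`` triplet) and
    ``meta.trial['analog-channel-map']`` (full column names) when present.
    The header as found in the file is preserved in
    ``df.attrs['original_header']``.
    """
    df = pd.read_csv(path, sep="\t")
    original = list(df.columns)
    for required in ("TimeStamp", "FrameNumber"):
        if required not in df.columns:
            raise FormatError(f"{path}: required column {required!r} missing from header")
    frames = df["FrameNumber"].to_numpy()
    if len(frames) > 1 and not np.all(np.diff(frames) > 0):
        raise IntegrityError(f"{path}: FrameNumber is not strictly increasing")
    df.columns = _relabel_columns(df.columns, meta)
    df.attrs["original_header"] = original
    return df


def infer_sample_times(mocap: pd.DataFrame) -> np.ndarray:
    """Uniform sample times derived from the frame counter.

    The acquisition time stamps jitter because of buffering, so the constant
    camera frame rate is estimated as the reciprocal of the median of
    ``dTimeStamp/dFrameNumber`` and sample times are laid out exactly linearly
    in frame number from the first time stamp::

        t[i] = t0 + (frame[i] - frame[0]) / rate
    """
    if len(mocap) < 2:
        raise IntegrityError("need at least 2 frames to infer sample times")
    t = mocap["TimeStamp"].to_numpy(dtype=float)
    f = mocap["FrameNumber"].to_numpy(dtype=float)
    slope = np.median(np.diff(t) / np.diff(f))
    if slope <= 0:
        raise IntegrityError(f"estimated frame period {slope} s is not positive")
    return t[0] + (f - f[0]) * slope


# ---------------------------------------------------------------------------
# record files
# ---------------------------------------------------------------------------

_EVENT_RE = re.compile(r"^#\s*(?:EVENT\s+)?.*?\b([A-Z])\b")


def _event_letter(comment: str) -> str | None:
    """First single-capital token in a ``#`` comment line, if any."""
    body = comment.lstrip("#").strip()
    for tok in body.replace(":", " ").split():
        if tok == "EVENT":
            continue
        if re.fullmatch(r"[A-Z]", tok):
            return tok
    return None


def parse_record(
    path: str | os.PathLike, meta: MetaData | None = None
) -> tuple[pd.DataFrame, EventTimeline]:
    """Parse a ``record-<nnn>.txt`` stream into data rows and events.

    ``#``-commented lines between data rows mark events; each event's time is
    the time of the first data row following the comment.  Letters are
    resolved to names through the meta events map; unmapped letters are kept
    with the name ``"unknown"`` and a warning.
    """
    events_map = meta.events if meta is not None else dict(DEFAULT_EVENTS)
    data_lines: list[str] = []
    pending: list[tuple[str, str]] = []  # (letter, raw comment) awaiting a data row
    found: list[tuple[str, str, int]] = []  # (letter, comment, data-row index)
    header: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.lstrip().startswith("#"):
                letter = _event_letter(line)
                if letter is not None:
                    pending.append((letter, line))
                continue
            if header is None:
                header = line
                continue
            for letter, comment in pending:
                found.append((letter, comment, len(data_lines)))
            pending.clear()
            data_lines.append(line)
    if header is None:
        raise FormatError(f"{path}: no header line found")
    df = pd.read_csv(StringIO(header + "\n" + "\n".join(data_lines)), sep="\t")
    if "Time" not in df.columns:
        raise FormatError(f"{path}: required column 'Time' missing from header")
    times = df["Time"].to_numpy(dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise IntegrityError(f"{path}: Time is not strictly increasing")
    timeline = EventTimeline()
    for letter, comment, idx in found:
        if idx >= len(times):  # trailing comment with no data row after it
            time = float(times[-1]) if len(times) else float("nan")
        else:
            time = float(times[idx])
        name = events_map.get(letter)
        if name is None:
            warnings.warn(f"{path}: event letter {letter!r} not in meta events map")
            name = "unknown"
        timeline.append(Event(letter, name, time))
    return df, timeline


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_cell(value) -> str:
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{float(value):.6f}"


def _write_tsv(df: pd.DataFrame, path: Path, comment_rows=None) -> None:
    """Write a data frame in the 6-decimal fixed-point tab dialect.

    ``comment_rows`` maps a data-row index to a list of comment lines to
    emit immediately before that row.
    """
    comment_rows = comment_rows or {}
    body = df.to_csv(sep="\t", float_format="%.6f", index=False,
                     lineterminator="\n")
    if not comment_rows:
        with open(path, "w", newline="\n") as fh:
            fh.write(body)
        return
    lines = body.splitlines()
    out = [lines[0]]
    for i, line in enumerate(lines[1:]):
        out.extend(comment_rows.get(i, ()))
        out.append(line)
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(out) + "\n")


def write_trial(bundle: TrialBundle, directory: str | os.PathLike) -> dict:
    """Write a trial directory ``T<nnn>/`` with the three standard files.

    Returns a mapping of file roles to written paths.  Numeric cells are
    fixed-point with six decimals; event comment lines are re-inserted before
    the data row whose time matches each event.
    """
    trial_id = bundle.meta.trial_id
    tdir = Path(directory) / f"T{trial_id:03d}"
    tdir.mkdir(parents=True, exist_ok=True)
    names = {
        "mocap": tdir / f"mocap-{trial_id:03d}.txt",
        "record": tdir / f"record-{trial_id:03d}.txt",
        "meta": tdir / f"meta-{trial_id:03d}.yml",
    }

    _write_tsv(bundle.mocap, names["mocap"])

    times = bundle.record["Time"].to_numpy(dtype=float)
    comment_rows: dict[int, list[str]] = {}
    for ev in bundle.events:
        idx = int(np.searchsorted(times, ev.time - 1e-9))
        idx = min(idx, len(times) - 1) if len(times) else 0
        comment_rows.setdefault(idx, []).append(f"# EVENT {ev.letter} {ev.name}")
    _write_tsv(bundle.record, names["record"], comment_rows)

    meta_dict = bundle.meta.to_dict()
    meta_dict.setdefault("trial", {})
    files = dict(meta_dict["trial"].get("files") or {})
    files.update({role: p.name for role, p in names.items()})
    meta_dict["trial"]["files"] = files
    with open(names["meta"], "w", newline="\n") as fh:
        yaml.safe_dump(meta_dict, fh, sort_keys=False, default_flow_style=False)

    return {role: str(p) for role, p in names.items()}


def read_trial(directory: str | os.PathLike) -> TrialBundle:
    """Read a ``T<nnn>/`` trial directory back into a :class:`TrialBundle`."""
    tdir = Path(directory)
    metas = sorted(tdir.glob("meta-*.yml"))
    if not metas:
        raise FileNotFoundError(f"no meta-*.yml in {tdir}")
    meta = parse_meta(metas[0], strict=False)
    files = meta.trial.get("files") or {}
    mocap_path = tdir / files.get("mocap", f"mocap-{meta.trial_id:03d}.txt")
    record_path = tdir / files.get("record", f"record-{meta.trial_id:03d}.txt")
    mocap = parse_mocap(mocap_path, meta)
    record, events = parse_record(record_path, meta)
    return TrialBundle(meta=meta, mocap=mocap, record=record, events=events)
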