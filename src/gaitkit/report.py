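"""Study-level subject summaries.

Aggregates per-trial meta files (or the packaged reference subject table)
into the usual participant summary: counts by gender, mean and sample SD of
age, height and mass, deduplicated by subject id.  Subject id 0 is the
"null subject" used for unloaded (no-subject) compensation trials and is
always excluded.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from gaitkit.trial_io import MetaData, parse_meta

__all__ = ["SubjectSummary", "summarize_subjects", "load_reference_subjects"]


def load_reference_subjects() -> pd.DataFrame:
    """The packaged study participant table (15 subjects).

    The ``mass`` column is the self-reported mass; ``measured_mass`` (with
    its SD) is present where it could be computed from the calibration-pose
    vertical GRF.
    """
    with resources.files("gaitkit.data").joinpath("study_subjects.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class SubjectSummary:
    """Participant summary with reporting-precision rounding.

    ``mass_source`` records whether the summarized masses were self-reported
    or GRF-measured.
    """

    n: int
    gender_counts: dict
    mean_age: float
    sd_age: float
    mean_height: float
    sd_height: float
    mean_mass: float
    sd_mass: float
    mass_source: str = "self-reported"
    per_subject: pd.DataFrame | None = None

    def rounded(self) -> dict:
        """Values at the reporting precision: age and mass as integers,
        height at two decimals."""
        return {
            "n": self.n,
            "gender_counts": dict(self.gender_counts),
            "mean_age": round(self.mean_age),
            "sd_age": round(self.sd_age),
            "mean_height": round(self.mean_height, 2),
            "sd_height": round(self.sd_height, 2),
            "mean_mass": round(self.mean_mass),
            "sd_mass": round(self.sd_mass),
        }


def _subjects_from_metas(meta_files) -> pd.DataFrame:
    rows = {}
    for item in meta_files:
        meta = item if isinstance(item, MetaData) else parse_meta(item, strict=False)
        subj = meta.subject
        sid = subj.get("id")
        if sid is None:
            warnings.warn(f"meta file without subject id skipped: {item}")
            continue
        rows[sid] = {
            "id": sid,
            "gender": subj.get("gender"),
            "age": subj.get("age"),
            "height": subj.get("height"),
            "mass": subj.get("mass"),
        }
    return pd.DataFrame(list(rows.values()))


def summarize_subjects(
    subjects: "pd.DataFrame | list", use_measured_mass: bool = False
) -> SubjectSummary:
    """Summarize study participants.

    ``subjects`` is either a subject table (like
    :func:`load_reference_subjects`) or an iterable of meta files /
    :class:`~gaitkit.trial_io.MetaData` objects, which are deduplicated by
    subject id.  Subjects with id 0 (unloaded trials) are excluded; subjects
    missing a required field are skipped with a warning.  Sample SDs use
    n - 1; with a single subject the SDs are NaN.
    """
    if not isinstance(subjects, pd.DataFrame):
        subjects = _subjects_from_metas(subjects)
    df = subjects.copy()
    df = df[df["id"] != 0]
    df = df.drop_duplicates(subset="id")
    mass_col = "mass"
    source = "self-reported"
    if use_measured_mass and "measured_mass" in df.columns:
        mass_col, source = "measured_mass", "measured"
    required = ["gender", "age", "height", mass_col]
    complete = df.dropna(subset=[c for c in required if c in df.columns])
    if len(complete) < len(df):
        warnings.warn(f"{len(df) - len(complete)} subject(s) skipped for missing fields")
    if complete.empty:
        raise ValueError("no complete subject records to summarize")

    def sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")

    return SubjectSummary(
        n=len(complete),
        gender_counts=complete["gender"].value_counts().to_dict(),
        mean_age=float(complete["age"].mean()),
        sd_age=sd(complete["age"]),
        mean_height=float(complete["height"].mean()),
        sd_height=sd(complete["height"]),
        mean_mass=float(complete[mass_col].mean()),
        sd_mass=sd(complete[mass_col]),
        mass_source=source,
        per_subject=complete.reset_index(drop=True),
    )
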