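"""Readers and writers for wrist-IMU CSV logs and the window store.

The CSV dialect is one row per timestamp with subject/activity/trial
identifier columns and six wrist channels (accelerometer x/y/z, gyroscope
x/y/z).  Column names are configurable through the ``columns`` mapping in
:class:`~fallaug.config.RunConfig` because public datasets disagree on
headers.  In the activity numbering of the target dataset, ids 1-5 are
fall types and 6-11 are activities of daily living.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_COLUMNS, DEFAULT_EXCLUSIONS
from .data import RawRecording, WindowDataset

log = logging.getLogger("fallaug")

#: activity ids labelled as falls in the target dataset's numbering
DEFAULT_FALL_ACTIVITIES = (1, 2, 3, 4, 5)


class FormatError(ValueError):
    """Raised when an input CSV does not match the expected dialect."""


def read_upfall_csv(path, columns: dict | None = None,
                    exclusions=DEFAULT_EXCLUSIONS,
                    fall_activities=DEFAULT_FALL_ACTIVITIES) -> list[RawRecording]:
    """Read a wrist-sensor CSV log into one recording per (subject, activity, trial).

    Rows are ordered by timestamp within each trial (a stable sort is
    applied with a warning if the file is not already monotonic), and
    trials on the exclusion list are dropped.
    """
    columns = columns or DEFAULT_COLUMNS
    df = pd.read_csv(path, float_precision="round_trip")
    needed = [columns["subject"], columns["activity"], columns["trial"],
              columns["timestamp"], *columns["channels"]]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        return []

    excluded = {tuple(map(int, t)) for t in exclusions}
    recordings = []
    keys = [columns["subject"], columns["activity"], columns["trial"]]
    for (subj, act, trial), grp in sorted(df.groupby(keys), key=lambda kv: kv[0]):
        key = (int(subj), int(act), int(trial))
        if key in excluded:
            log.info("excluding trial %s per exclusion list", key)
            continue
        ts = grp[columns["timestamp"]].to_numpy()
        if np.any(np.diff(ts) < 0):
            warnings.warn(f"non-monotonic timestamps in trial {key}; applying stable sort")
            grp = grp.sort_values(columns["timestamp"], kind="stable")
        samples = grp[columns["channels"]].to_numpy(dtype=float)
        recordings.append(RawRecording(
            subject_id=key[0], activity_id=key[1], trial_id=key[2],
            samples=samples, is_fall=key[1] in set(fall_activities)))
    return recordings


def write_upfall_csv(recordings: list[RawRecording], path,
                     columns: dict | None = None) -> None:
    """Export recordings to the same CSV dialect the reader accepts."""
    columns = columns or DEFAULT_COLUMNS
    frames = []
    for rec in recordings:
        n = rec.n_samples
        frame = pd.DataFrame(rec.samples, columns=columns["channels"])
        frame.insert(0, columns["timestamp"], np.arange(n) / rec.sampling_rate_hz)
        frame.insert(0, columns["trial"], rec.trial_id)
        frame.insert(0, columns["activity"], rec.activity_id)
        frame.insert(0, columns["subject"], rec.subject_id)
        frames.append(frame)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=[columns["subject"], columns["activity"],
                                      columns["trial"], columns["timestamp"],
                                      *columns["channels"]]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def save_dataset(dataset: WindowDataset, path) -> None:
    dataset.save(path)


def load_dataset(path) -> WindowDataset:
    return WindowDataset.load(path)
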