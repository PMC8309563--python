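"""Reading and writing labelled accelerometer trials.

A trial is stored as a 10-column CSV: ``Index``, ``Participant number``,
``Participant reference``, ``Trial number``, ``Timestamp``, ``Ax``,
``Ay``, ``Az``, ``An``, ``activity name``.  Accelerations are in g;
``An`` is the Euclidean norm of the three axes and is recomputed on read
if absent or inconsistent.  Timestamps are serialised as integer
milliseconds since trial start; wall-clock strings of the form
``YYYY-mm-dd HH:MM:SS.FFF`` are accepted on read and normalised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activities import TRANSITION_LABEL

logger = logging.getLogger(__name__)

#: Exact column order of the on-disk schema.
CSV_COLUMNS = (
    "Index",
    "Participant number",
    "Participant reference",
    "Trial number",
    "Timestamp",
    "Ax",
    "Ay",
    "Az",
    "An",
    "activity name",
)

#: Tolerance (g) beyond which a stored An column is considered
#: inconsistent with the norm of the axes and is recomputed.
_NORM_TOLERANCE = 1e-4


class SchemaError(ValueError):
    """Raised when a CSV file does not follow the 10-column trial schema."""


def compute_norm(ax, ay, az):
    """Euclidean norm ``sqrt(Ax^2 + Ay^2 + Az^2)`` of the three axes.

    Accepts scalars or arrays (broadcast elementwise).  Raises
    ``ValueError`` on non-finite input.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise ValueError("compute_norm requires finite inputs")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class LabelInterval:
    """Half-open labelled time interval ``[start, end)`` in milliseconds."""

    start: int
    end: int
    label: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")


@dataclass
class Recording:
    """One subject/trial multichannel labelled acceleration stream.

    All channel arrays share a common length N; timestamps are strictly
    increasing milliseconds.
    """

    subject_id: int
    trial_no: int
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    an: np.ndarray = None
    labels: np.ndarray = None
    participant_ref: str = field(default="")

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.timestamps)
        if self.an is None:
            self.an = compute_norm(self.ax, self.ay, self.az)
        self.an = np.asarray(self.an, dtype=float)
        if self.labels is None:
            self.labels = np.full(n, TRANSITION_LABEL, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        for name in ("ax", "ay", "az", "an", "labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from timestamps")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.participant_ref:
            self.participant_ref = f"P{self.subject_id:02d}"

    def __len__(self):
        return len(self.timestamps)

    def channel_matrix(self):
        """Samples as an N x 4 array in (Ax, Ay, Az, An) order."""
        return np.column_stack([self.ax, self.ay, self.az, self.an])


def apply_labels(rec: Recording, intervals: list[LabelInterval]) -> Recording:
    """Assign per-sample labels from sorted, non-overlapping intervals.

    A sample at time t gets the label of the interval with
    ``start <= t < end``; samples covered by no interval are labelled
    ``transition``.  Returns a new Recording; the input is unchanged.
    """
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping intervals: [{a.start},{a.end}) and [{b.start},{b.end})"
            )
    labels = np.full(len(rec), TRANSITION_LABEL, dtype=object)
    for iv in ivs:
        mask = (rec.timestamps >= iv.start) & (rec.timestamps < iv.end)
        labels[mask] = iv.label
    return replace(rec, labels=labels)


def write_recording(rec: Recording, path) -> None:
    """Serialise a Recording to the 10-column CSV schema."""
    df = pd.DataFrame(
        {
            "Index": np.arange(len(rec), dtype=np.int64),
            "Participant number": rec.subject_id,
            "Participant reference": rec.participant_ref,
            "Trial number": rec.trial_no,
            "Timestamp": rec.timestamps,
            "Ax": rec.ax,
            "Ay": rec.ay,
            "Az": rec.az,
            "An": rec.an,
            "activity name": rec.labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def _parse_timestamps(col: pd.Series) -> np.ndarray:
    """Timestamps as int64 ms since trial start; accepts wall-clock strings."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=np.int64)
    ts = pd.to_datetime(col, format="mixed")
    delta = ts - ts.iloc[0]
    return (delta.dt.total_seconds() * 1000).round().to_numpy(dtype=np.int64)


def read_recording(path) -> Recording:
    """Load a Recording from CSV, validating the schema.

    A missing ``An`` column is filled from the axes; an inconsistent one
    triggers a warning and is recomputed.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "An"]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    timestamps = _parse_timestamps(df["Timestamp"])
    ax = df["Ax"].to_numpy(dtype=float)
    ay = df["Ay"].to_numpy(dtype=float)
    az = df["Az"].to_numpy(dtype=float)
    an_true = compute_norm(ax, ay, az)
    if "An" in df.columns:
        an = df["An"].to_numpy(dtype=float)
        if np.max(np.abs(an - an_true)) > _NORM_TOLERANCE:
            warnings.warn(
                "An column inconsistent with the Euclidean norm of the axes; recomputing",
                stacklevel=2,
            )
            an = an_true
    else:
        an = an_true
    return Recording(
        subject_id=int(df["Participant number"].iloc[0]),
        trial_no=int(df["Trial number"].iloc[0]),
        timestamps=timestamps,
        ax=ax,
        ay=ay,
        az=az,
        an=an,
        labels=df["activity name"].to_numpy(dtype=object),
        participant_ref=str(df["Participant reference"].iloc[0]),
    )
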