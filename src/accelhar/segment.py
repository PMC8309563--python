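"""Sliding-window segmentation and leave-one-subject-out fold planning.

Streams are cut by a fixed-size overlapping sliding window (FOSW): with
window length T samples and overlap fraction o, window k starts at
``k * stride`` with ``stride = round(T * (1 - o))``.  Windows whose
samples carry more than one distinct label (impure windows at activity
boundaries) are discarded, as are windows labelled with any class in
``drop_labels`` (the transitional class by default).  Segmentation is
always applied after the train/test split so no window mixes subjects
or leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activities import TRANSITION_LABEL
from .dataio import Recording


@dataclass
class SegmentTensor:
    """K windows of T samples over m channels with one label each."""

    values: np.ndarray      # K x T x m
    labels: np.ndarray      # K object
    subject_ids: np.ndarray  # K int
    trial_ids: np.ndarray   # K int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        if self.values.ndim != 3:
            raise ValueError("values must be K x T x m")
        k = self.values.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == len(self.trial_ids) == k):
            raise ValueError("metadata length mismatch with K")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def window_length(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def __len__(self):
        return self.n_segments

    @classmethod
    def concatenate(cls, tensors: list["SegmentTensor"]) -> "SegmentTensor":
        tensors = [t for t in tensors if t.n_segments > 0]
        if not tensors:
            raise ValueError("no non-empty tensors to concatenate")
        return cls(
            np.concatenate([t.values for t in tensors]),
            np.concatenate([t.labels for t in tensors]),
            np.concatenate([t.subject_ids for t in tensors]),
            np.concatenate([t.trial_ids for t in tensors]),
        )

    def save_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            labels=self.labels.astype(str),
            subject_ids=self.subject_ids,
            trial_ids=self.trial_ids,
        )

    @classmethod
    def load_npz(cls, path) -> "SegmentTensor":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                data["values"],
                data["labels"].astype(object),
                data["subject_ids"],
                data["trial_ids"],
            )


@dataclass(frozen=True)
class FoldPlan:
    """Ordered leave-one-subject-out folds: one (train set, test id) per
    subject, test subjects in ascending order."""

    folds: tuple[tuple[frozenset, int], ...]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_fold_plan(subject_ids) -> FoldPlan:
    """One fold per subject; each subject is the test subject exactly once."""
    ids = sorted(set(int(s) for s in subject_ids))
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = tuple(
        (frozenset(s for s in ids if s != test), test) for test in ids
    )
    return FoldPlan(folds)


def window_starts(n: int, window: int, stride: int) -> np.ndarray:
    """Start indices of all full windows: 0, stride, ... while start+window <= n."""
    if n < window:
        return np.empty(0, dtype=int)
    k = (n - window) // stride + 1
    return np.arange(k) * stride


def segment_recording(
    rec: Recording,
    window_seconds: float = 1.0,
    overlap: float = 0.5,
    fs: float = 64.0,
    drop_labels=(TRANSITION_LABEL,),
) -> SegmentTensor:
    """Windowed K x T x 4 tensor of (Ax, Ay, Az, An) with pure labels.

    T = round(fs * window_seconds); stride = round(T * (1 - overlap)).
    Impure windows (more than one distinct sample label) and windows
    whose label is in ``drop_labels`` are discarded.  A stream shorter
    than one window yields K = 0, not an error.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    t_len = int(round(fs * window_seconds))
    if t_len < 1:
        raise ValueError("window must cover at least one sample")
    stride = max(1, int(round(t_len * (1 - overlap))))
    data = rec.channel_matrix()
    starts = window_starts(len(rec), t_len, stride)
    drop = set(drop_labels)

    windows, labels = [], []
    for s in starts:
        lab = rec.labels[s : s + t_len]
        first = lab[0]
        if first in drop:
            continue
        if not all(x == first for x in lab):
            continue
        windows.append(data[s : s + t_len].copy())
        labels.append(first)

    k = len(windows)
    values = np.stack(windows) if k else np.empty((0, t_len, data.shape[1]))
    return SegmentTensor(
        values=values,
        labels=np.array(labels, dtype=object),
        subject_ids=np.full(k, rec.subject_id),
        trial_ids=np.full(k, rec.trial_no),
    )


def segment_recordings(recordings, **kwargs) -> SegmentTensor:
    """Segment each recording independently and stack the results."""
    tensors = [segment_recording(r, **kwargs) for r in recordings]
    tensors = [t for t in tensors if t.n_segments > 0]
    if not tensors:
        t_len = int(round(kwargs.get("fs", 64.0) * kwargs.get("window_seconds", 1.0)))
        return SegmentTensor(
            np.empty((0, t_len, 4)), np.empty(0, dtype=object),
            np.empty(0, dtype=int), np.empty(0, dtype=int),
        )
    return SegmentTensor.concatenate(tensors)
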