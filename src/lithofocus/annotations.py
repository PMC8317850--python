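"""Interval annotation scheme and per-frame label files.

Because a stone stays in or out of the focal zone for runs of consecutive
frames, annotators mark only the transition points: each record gives the
0-based frame at which a new in/out interval starts.  Expansion turns such
a transition list into one label per frame; compression is its inverse.
All frame indices are 0-based (clinical narration such as "the tenth
frame" is 1-based and converted at the I/O boundary by the caller).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .focus import IN_FOCUS, OUT_OF_FOCUS

__all__ = [
    "IntervalLabel",
    "FrameLabels",
    "expand_intervals",
    "compress_labels",
    "sample_window",
    "corrupt_labels",
    "write_labels_csv",
    "read_labels_csv",
    "write_intervals_csv",
    "read_intervals_csv",
]

_LABEL_TO_INT = {OUT_OF_FOCUS: 0, IN_FOCUS: 1}
_INT_TO_LABEL = {0: OUT_OF_FOCUS, 1: IN_FOCUS}


@dataclass(frozen=True)
class IntervalLabel:
    """A transition record: from ``start_frame`` on, frames carry ``label``."""

    start_frame: int
    label: str

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise ValueError("start_frame must be non-negative")
        if self.label not in _LABEL_TO_INT:
            raise ValueError(f"label must be {IN_FOCUS!r} or {OUT_OF_FOCUS!r}")


@dataclass
class FrameLabels:
    """Per-frame binary labels for one patient's video segment.

    ``labels[i]`` is 1 when the stone is in the focal zone in frame i and
    0 otherwise.
    """

    labels: np.ndarray
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be 0 (out of focus) or 1 (in focus)")
        self.labels = arr

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_focus(self) -> int:
        """Number of frames labelled in-focus (the operator's hit count)."""
        return int(self.labels.sum())


def _validate_intervals(intervals: Sequence[IntervalLabel]) -> None:
    if not intervals:
        raise ValueError("interval list is empty")
    starts = [iv.start_frame for iv in intervals]
    if starts[0] != 0:
        raise ValueError("first interval must start at frame 0")
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("interval start_frames must be strictly increasing")


def expand_intervals(
    intervals: Sequence[IntervalLabel], n_frames: int, patient_id: str = "unknown"
) -> FrameLabels:
    """Expand transition records into one label per frame.

    Frame i carries the label of the latest interval starting at or before
    i; the final interval extends to the end of the video.
    """
    _validate_intervals(intervals)
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if intervals[-1].start_frame >= n_frames:
        raise ValueError("last interval starts beyond the video length")
    labels = np.empty(n_frames, dtype=np.int8)
    starts = [iv.start_frame for iv in intervals] + [n_frames]
    for iv, stop in zip(intervals, starts[1:]):
        labels[iv.start_frame : stop] = _LABEL_TO_INT[iv.label]
    return FrameLabels(labels, patient_id)


def compress_labels(labels: FrameLabels) -> List[IntervalLabel]:
    """Inverse of :func:`expand_intervals`: recover the transition records."""
    arr = labels.labels
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    return [IntervalLabel(int(s), _INT_TO_LABEL[int(arr[s])]) for s in starts]


def sample_window(
    total_frames: int, window_frames: int, seed: int | np.random.Generator = 0
) -> int:
    """Uniformly sample the start frame of an annotation window.

    Emulates picking a fixed-length sequence at random from a longer
    treatment video; the start index is uniform on [0, total − window].
    """
    if window_frames <= 0 or total_frames <= 0:
        raise ValueError("frame counts must be positive")
    if window_frames > total_frames:
        raise ValueError("window is longer than the video")
    rng = np.random.default_rng(seed)
    return int(rng.integers(0, total_frames - window_frames + 1))


def corrupt_labels(
    labels: FrameLabels, mismatch_rate: float, seed: int | np.random.Generator = 0
) -> FrameLabels:
    """Flip each frame label independently with probability ``mismatch_rate``.

    Emulates interobserver disagreement between two annotators; at rate r
    the expected fraction of mismatching frames is exactly r.
    """
    if not 0.0 <= mismatch_rate <= 1.0:
        raise ValueError("mismatch_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flip = rng.random(len(labels)) < mismatch_rate
    out = labels.labels.copy()
    out[flip] = 1 - out[flip]
    return FrameLabels(out, labels.patient_id)


# ---------------------------------------------------------------------------
# CSV dialects: expanded labels (one row per frame) and interval form.


def write_labels_csv(labels: Sequence[FrameLabels], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "patient_id": fl.patient_id,
                "frame_index": np.arange(len(fl)),
                "label": fl.labels,
            }
        )
        for fl in labels
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> List[FrameLabels]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("frame_index")
        if not (grp["frame_index"].to_numpy() == np.arange(len(grp))).all():
            raise ValueError(f"patient {pid}: frame indices are not contiguous")
        out.append(FrameLabels(grp["label"].to_numpy(), str(pid)))
    return out


def write_intervals_csv(
    intervals: Sequence[IntervalLabel], path: str | Path, patient_id: str = "unknown"
) -> None:
    pd.DataFrame(
        {
            "patient_id": patient_id,
            "start_frame": [iv.start_frame for iv in intervals],
            "label": [_LABEL_TO_INT[iv.label] for iv in intervals],
        }
    ).to_csv(path, index=False)


def read_intervals_csv(path: str | Path) -> dict[str, List[IntervalLabel]]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out: dict[str, List[IntervalLabel]] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("start_frame")
        out[str(pid)] = [
            IntervalLabel(int(s), _INT_TO_LABEL[int(l)])
            for s, l in zip(grp["start_frame"], grp["label"])
        ]
    return out
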