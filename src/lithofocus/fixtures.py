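"""Packaged reference data from the 11-patient clinical ESWL cohort.

The raw ultrasound videos are private patient data; what is public, and
shipped here, are the aggregate counts: the test-set confusion matrix of
the stone segmenter, the per-patient frames-in-focus tallies (three
patients whose stones were not visible on ultrasound are marked
excluded), and the published summary values the pipeline reproduces.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List

import pandas as pd

from .evaluation import ConfusionMatrix
from .hitrate import PatientFrames

__all__ = [
    "reference_confusion",
    "reference_patient_frames",
    "reference_patient_table",
    "reference_summary",
]


def _data(name: str):
    return resources.files("lithofocus.data").joinpath(name)


def reference_confusion() -> ConfusionMatrix:
    """Test-set confusion matrix of the clinical stone segmenter."""
    df = pd.read_csv(_data("confusion_counts.csv").open())
    row = df.iloc[0]
    return ConfusionMatrix(
        tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn)
    )


def reference_patient_table() -> pd.DataFrame:
    """Per-patient frame tallies, including the excluded patients."""
    df = pd.read_csv(_data("patient_frame_counts.csv").open(), dtype={"patient_id": str})
    return df


def reference_patient_frames() -> List[PatientFrames]:
    """The analyzable patients (excluded rows dropped)."""
    df = reference_patient_table()
    df = df[df["included"] == 1]
    return [
        PatientFrames(str(r.patient_id), int(r.n_focus), int(r.n_total))
        for r in df.itertuples()
    ]


def reference_summary() -> Dict:
    """Published summary values used as reproduction targets."""
    with _data("reference_summary.json").open() as fh:
        return json.load(fh)
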