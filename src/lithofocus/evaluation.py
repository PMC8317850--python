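"""Classifier diagnostics and treatment-efficiency estimates.

The gating decisions form a binary classifier against the annotator's
per-frame ground truth; this module builds the confusion matrix and the
standard metric suite (accuracy, sensitivity, specificity, PPV, NPV,
prevalence, detection rate and prevalence, balanced accuracy, Youden's J,
the no-information rate, and Cohen's κ).  PPV has a direct clinical
meaning here: it is the hit rate achieved if the lithotripter fires only
on frames the algorithm calls in-focus.

The efficiency estimates translate the matrix into treatment terms at a
constant pulse rate: gated firing skips frames, so delivering the same
number of hits takes longer (relative treatment time = annotated
in-focus frames / true positives), but far fewer shots land outside the
stone.  The mishit ratio scales the false-positive count by that time
stretch against the operator's out-of-focus exposure; note the
time-stretch factor multiplies the false positives — shots fired when
the stone is out of focus — not the true negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .focus import NO_DETECTION, FocusCall

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "EfficiencyReport",
    "confusion",
    "metrics",
    "efficiency",
    "alternative_policy_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Frame counts with decisions on rows and annotator truth on columns:
    tp = in-focus called in-focus, fp = out-of-focus called in-focus,
    fn = in-focus called out-of-focus, tn = out-of-focus called out-of-focus.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """The full metric suite as fractions (κ dimensionless in [−1, 1]).

    Undefined ratios (zero denominators) are reported as NaN rather than
    raised, so degenerate runs still produce a report.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float
    youden_j: float
    no_information_rate: float
    kappa: float

    def as_percent_dict(self) -> dict:
        """Display form: percentages to one decimal, κ to four decimals."""
        out = {
            k: (round(v * 100, 1) if not math.isnan(v) else float("nan"))
            for k, v in self.__dict__.items()
            if k != "kappa"
        }
        out["kappa"] = round(self.kappa, 4) if not math.isnan(self.kappa) else float("nan")
        return out


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion(decisions: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Cross-tabulate binary gating decisions against annotator truth."""
    d = np.asarray(decisions, dtype=int)
    t = np.asarray(truth, dtype=int)
    if d.shape != t.shape or d.ndim != 1:
        raise ValueError("decisions and truth must be equal-length 1-D sequences")
    return ConfusionMatrix(
        tp=int(((d == 1) & (t == 1)).sum()),
        fp=int(((d == 1) & (t == 0)).sum()),
        fn=int(((d == 0) & (t == 1)).sum()),
        tn=int(((d == 0) & (t == 0)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Compute the metric suite from a confusion matrix.

    Cohen's κ is (p_o − p_e)/(1 − p_e) with the expected agreement p_e
    taken from the row/column marginals.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.total
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prev = (tp + fn) / n
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _ratio(p_o - p_e, 1.0 - p_e)
    return MetricReport(
        accuracy=p_o,
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        prevalence=prev,
        detection_rate=tp / n,
        detection_prevalence=(tp + fp) / n,
        balanced_accuracy=(sens + spec) / 2.0,
        youden_j=sens + spec - 1.0,
        no_information_rate=max(prev, 1.0 - prev),
        kappa=kappa,
    )


@dataclass(frozen=True)
class EfficiencyReport:
    """Gated vs operator-controlled treatment efficiency.

    ``relative_treatment_time`` is how much longer gated firing takes to
    deliver the operator's hit count; ``mishit_ratio`` is the gated
    mishit exposure as a fraction of the operator's, and
    ``mishit_reduction`` its complement.  Hits/min assume the lithotripter
    fires continuously at ``pulse_rate``.
    """

    relative_treatment_time: float
    mishit_ratio: float
    mishit_reduction: float
    hits_per_minute_operator: float
    hits_per_minute_ai: float
    pulse_rate: float = 90.0
    #: The time-stretch factor is applied to the false-positive count
    #: (shots fired while the stone is out of focus).
    mishit_basis: str = field(default="false_positives", compare=False)


def efficiency(
    cm: ConfusionMatrix,
    n_focus_annot: int,
    n_out_annot: int,
    pulse_rate: float = 90.0,
) -> EfficiencyReport:
    """Estimate gated-treatment efficiency from the confusion matrix.

    ``n_focus_annot`` and ``n_out_annot`` are the annotator's in-focus and
    out-of-focus frame counts over the *whole* annotated video (including
    frames the detector later dropped), which is why they are passed
    separately rather than read off the matrix marginals.
    """
    if n_out_annot <= 0 or n_focus_annot < 0:
        raise ValueError("annotated frame counts invalid")
    if cm.tp == 0:
        nan = float("nan")
        return EfficiencyReport(nan, nan, nan, nan, nan, pulse_rate)
    rtt = n_focus_annot / cm.tp
    mishit = rtt * cm.fp / n_out_annot
    n_annot = n_focus_annot + n_out_annot
    return EfficiencyReport(
        relative_treatment_time=rtt,
        mishit_ratio=mishit,
        mishit_reduction=1.0 - mishit,
        hits_per_minute_operator=pulse_rate * n_focus_annot / n_annot,
        hits_per_minute_ai=pulse_rate * cm.tp / n_annot,
        pulse_rate=pulse_rate,
    )


def alternative_policy_report(
    calls: Sequence[FocusCall], truth: Sequence[int]
) -> MetricReport:
    """Metric suite when no-detection frames count as out-of-focus.

    The conservative policy: an undetected stone is never fired upon, so
    every no-detection frame becomes an out-of-focus decision over the
    full frame set (nothing is excluded).  Sensitivity can only drop
    relative to the exclusion policy — false negatives grow — while
    specificity and accuracy typically improve.
    """
    calls = list(calls)
    t = np.asarray(truth, dtype=int)
    if len(calls) != len(t):
        raise ValueError("calls and truth must have equal length")
    decisions = [0 if c.value == NO_DETECTION else (1 if c.value == "in_focus" else 0) for c in calls]
    return metrics(confusion(decisions, t))
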