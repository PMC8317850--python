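"""Metric suite, efficiency arithmetic, policy comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lithofocus.evaluation import (
    ConfusionMatrix,
    alternative_policy_report,
    confusion,
    efficiency,
    metrics,
)
from lithofocus.fixtures import reference_confusion
from lithofocus.focus import FocusCall


def test_published_confusion_matrix_metrics():
    rep = metrics(reference_confusion()).as_percent_dict()
    assert rep["accuracy"] == 63.9
    assert rep["sensitivity"] == 56.0
    assert rep["specificity"] == 74.7
    assert rep["ppv"] == 75.3
    assert rep["npv"] == 55.2
    assert rep["prevalence"] == 58.0
    assert rep["detection_rate"] == 32.5
    assert rep["detection_prevalence"] == 43.1
    assert rep["balanced_accuracy"] == 65.4
    assert rep["youden_j"] == 30.7
    assert rep["no_information_rate"] == 58.0
    assert rep["kappa"] == 0.2931


def test_perfect_and_chance_level_classifiers():
    perfect = metrics(ConfusionMatrix(50, 0, 0, 50))
    assert perfect.accuracy == 1.0 and perfect.kappa == 1.0 and perfect.youden_j == 1.0
    chance = metrics(ConfusionMatrix(25, 25, 25, 25))
    assert chance.kappa == pytest.approx(0.0, abs=1e-12)
    assert chance.youden_j == pytest.approx(0.0, abs=1e-12)


def test_kappa_cross_checked_against_sklearn():
    from sklearn.metrics import cohen_kappa_score

    cm = reference_confusion()
    decisions = [1] * cm.tp + [1] * cm.fp + [0] * cm.fn + [0] * cm.tn
    truth = [1] * cm.tp + [0] * cm.fp + [1] * cm.fn + [0] * cm.tn
    assert metrics(cm).kappa == pytest.approx(
        cohen_kappa_score(truth, decisions), abs=1e-12
    )


def test_confusion_construction_and_transpose_symmetry():
    decisions = [1, 1, 0, 0, 1]
    truth = [1, 0, 1, 0, 1]
    cm = confusion(decisions, truth)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 1)
    swapped = confusion(truth, decisions)
    assert (swapped.fp, swapped.fn) == (cm.fn, cm.fp)
    with pytest.raises(ValueError):
        confusion([1, 0], [1])


@settings(max_examples=200, deadline=None)
@given(st.tuples(*[st.integers(0, 2000)] * 4).filter(lambda t: sum(t) > 0))
def test_metric_identities_hold_for_any_matrix(counts):
    rep = metrics(ConfusionMatrix(*counts))
    if not (math.isnan(rep.sensitivity) or math.isnan(rep.specificity)):
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )
        assert rep.youden_j == pytest.approx(rep.sensitivity + rep.specificity - 1)
    assert rep.no_information_rate == pytest.approx(
        max(rep.prevalence, 1 - rep.prevalence)
    )
    assert rep.detection_rate <= rep.prevalence + 1e-12
    assert rep.detection_rate <= rep.detection_prevalence + 1e-12
    if not math.isnan(rep.kappa):
        assert -1.0 - 1e-12 <= rep.kappa <= 1.0 + 1e-12


def test_efficiency_reproduces_published_arithmetic():
    eff = efficiency(reference_confusion(), n_focus_annot=11_633,
                     n_out_annot=23_212 - 11_633)
    assert round(eff.relative_treatment_time, 2) == 1.94
    assert round(eff.mishit_ratio * 100, 1) == 32.9
    assert round(eff.mishit_reduction * 100, 1) == 67.1
    assert round(eff.hits_per_minute_operator) == 45
    assert round(eff.hits_per_minute_ai) == 23
    assert eff.hits_per_minute_operator <= eff.pulse_rate
    assert eff.hits_per_minute_ai <= eff.pulse_rate


def test_perfect_classifier_efficiency_is_ideal():
    cm = ConfusionMatrix(tp=600, fp=0, fn=0, tn=400)
    eff = efficiency(cm, n_focus_annot=600, n_out_annot=400)
    assert eff.relative_treatment_time == 1.0
    assert eff.mishit_ratio == 0.0
    assert eff.mishit_reduction == 1.0


def test_zero_true_positives_reported_as_nan():
    eff = efficiency(ConfusionMatrix(0, 5, 10, 5), 10, 10)
    assert math.isnan(eff.relative_treatment_time)
    assert math.isnan(eff.mishit_ratio)


def test_ppv_equals_gated_firing_hit_rate():
    """Firing only on in-focus decisions yields a hit fraction equal to
    the PPV, by direct simulation of the decision stream."""
    rng = np.random.default_rng(7)
    truth = rng.integers(0, 2, size=5000)
    noisy = np.where(rng.random(5000) < 0.3, 1 - truth, truth)
    cm = confusion(noisy, truth)
    fired = noisy == 1
    hit_fraction = truth[fired].mean()
    assert hit_fraction == pytest.approx(metrics(cm).ppv)


def test_alternative_policy_reconstruction():
    """Relabeling undetected frames as out-of-focus over all 23 212
    frames: false negatives and true negatives absorb the undetected
    in-focus (946) and out-of-focus (3 826) frames."""
    cm = reference_confusion()
    nd_focus = 11_633 - (cm.tp + cm.fn)  # 946
    nd_out = (23_212 - 11_633) - (cm.fp + cm.tn)  # 3826
    calls = (
        [FocusCall("in_focus", 0.9)] * (cm.tp + cm.fp)
        + [FocusCall("out_of_focus", 0.1)] * (cm.fn + cm.tn)
        + [FocusCall("no_detection")] * (nd_focus + nd_out)
    )
    truth = (
        [1] * cm.tp + [0] * cm.fp + [1] * cm.fn + [0] * cm.tn
        + [1] * nd_focus + [0] * nd_out
    )
    rep = alternative_policy_report(calls, truth)
    assert round(rep.sensitivity * 100, 1) == 51.5
    assert round(rep.specificity * 100, 1) == 83.1
    # sensitivity can only drop relative to the exclusion policy
    assert rep.sensitivity <= metrics(cm).sensitivity
    # with no undetected frames both policies coincide
    rep2 = alternative_policy_report(calls[: cm.total], truth[: cm.total])
    assert rep2 == metrics(cm)
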