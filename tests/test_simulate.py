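"""Simulator contracts: motion, rendering, labels, cohort heterogeneity."""

import dataclasses
import math

import numpy as np
import pytest

from lithofocus.focus import FocalZone, classify_frame
from lithofocus.hitrate import PatientFrames, pooling_chi2
from lithofocus.simulate import (
    SimConfig,
    generate_sequence,
    render_frame,
    respiratory_trajectory,
    simulate_cohort,
)


def test_trajectory_is_periodic_with_respiratory_period():
    # 4 s period at 15 frames/s = 60 frames per cycle, exactly repeatable
    cfg = SimConfig(duration=8.0, respiratory_period=4.0)
    tr = respiratory_trajectory(cfg)
    np.testing.assert_allclose(tr.positions[:60], tr.positions[60:120], atol=1e-9)


def test_trajectory_length_is_frame_rate_times_duration():
    assert len(respiratory_trajectory(SimConfig(duration=60.0))) == 900


@pytest.mark.parametrize("p", [1.5, 2.0, 4.0])
def test_end_expiration_dwell_slower_than_mid_cycle(p):
    """Displacement per frame near the dwell is below the mid-cycle speed."""
    cfg = SimConfig(duration=4.0, dwell_exponent=p)
    pos = respiratory_trajectory(cfg).positions
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    n = len(step)
    dwell = np.r_[step[: n // 10], step[-n // 10 :]]  # around t=0 and t=T
    mid = step[n // 2 - n // 20 : n // 2 + n // 20]  # around mid-cycle
    assert dwell.mean() < mid.mean()


def test_higher_dwell_exponent_concentrates_frames_at_extremum():
    """Fraction of frames within 1 px of end-expiration grows with the
    exponent, counted directly over one period."""

    def frac_near_extremum(p):
        cfg = SimConfig(duration=4.0, dwell_exponent=p)
        pos = respiratory_trajectory(cfg).positions
        extremum = pos[0]
        dist = np.linalg.norm(pos - extremum, axis=1)
        return np.mean(dist < 1.0)

    assert frac_near_extremum(4.0) > frac_near_extremum(1.0)


def test_invalid_motion_parameters_rejected():
    with pytest.raises(ValueError):
        SimConfig(respiratory_period=0.0)
    with pytest.raises(ValueError):
        SimConfig(motion_amplitude=-1.0)
    with pytest.raises(ValueError):
        SimConfig(dwell_exponent=0.5)
    with pytest.raises(ValueError):
        SimConfig(motion_amplitude=500.0)  # stone would leave the image


def test_rendered_frame_ground_truth_and_masks():
    cfg = SimConfig(duration=4.0)
    tr = respiratory_trajectory(cfg)
    pk = render_frame(tr, 0, cfg)  # frame 0 is the dwell: stone at FZ centre
    assert pk.true_overlap == 1.0
    assert pk.true_label == "in_focus"
    assert pk.image.dtype == np.uint8
    assert pk.stone_mask.any() and pk.kidney_mask.any()
    # stone pixel count close to the ellipse area pi*a*b
    a, b = cfg.stone_axes
    assert abs(pk.stone_mask.sum() - math.pi * a * b) <= 0.15 * math.pi * a * b


def test_zone_smaller_than_stone_never_reaches_half_overlap():
    # a focal zone smaller than the stone cannot contain half of it, so
    # every frame is out of focus; mid-cycle frames are fully outside
    fz = FocalZone(center=(32.0, 28.0), semi_axes=(1.5, 1.5))
    cfg = dataclasses.replace(SimConfig(duration=4.0), focal_zone=fz)
    packets, labels = generate_sequence(cfg)
    assert labels.labels.sum() == 0
    assert max(p.true_overlap for p in packets) < 0.5
    assert min(p.true_overlap for p in packets) == 0.0


def test_sequence_determinism_and_label_consistency():
    cfg = SimConfig(duration=3.0, seed=7)
    pk1, lab1 = generate_sequence(cfg)
    pk2, lab2 = generate_sequence(cfg)
    assert np.array_equal(lab1.labels, lab2.labels)
    for p, q in zip(pk1, pk2):
        assert np.array_equal(p.image, q.image)
    # generator labels agree with the gating rule applied to its own masks
    for p in pk1:
        call = classify_frame(p.stone_mask, cfg.focal_zone)
        assert call.value == p.true_label


def test_cohort_requires_three_patients_and_is_seeded():
    with pytest.raises(ValueError):
        simulate_cohort(2, 0.5, seed=0)
    a = simulate_cohort(3, 0.8, seed=5, base_config=SimConfig(duration=2.0))
    b = simulate_cohort(3, 0.8, seed=5, base_config=SimConfig(duration=2.0))
    for pid in a:
        assert np.array_equal(a[pid][2].labels, b[pid][2].labels)


def test_zero_jitter_cohort_is_homogeneous(small_cohort):
    base = SimConfig(duration=80 / 15.0)
    cohort = simulate_cohort(4, 0.0, seed=9, base_config=base)
    rates = [lab.n_focus / len(lab) for _, _, lab in cohort.values()]
    assert len(set(rates)) == 1
    pf = [PatientFrames(pid, lab.n_focus, len(lab)) for pid, (_, _, lab) in cohort.items()]
    decision = pooling_chi2(pf)
    assert decision.chi2 == pytest.approx(0.0, abs=1e-9)
    assert decision.pooled


def test_strong_jitter_cohort_rejects_pooling(cohort11):
    pf = [
        PatientFrames(pid, lab.n_focus, len(lab))
        for pid, (_, _, lab) in cohort11.items()
    ]
    rates = [p.n_focus / p.n_total for p in pf]
    assert max(rates) - min(rates) > 0.2  # heterogeneous by construction
    decision = pooling_chi2(pf, alpha=0.05)
    assert not decision.pooled
    assert decision.p_value < 0.05


def test_eleven_patient_cohort_supports_nine_one_one_split(cohort11):
    assert len(cohort11) == 11  # 9 train + 1 val + 1 test per fold


def test_simconfig_yaml_roundtrip(tmp_path):
    cfg = SimConfig(duration=2.0, dwell_offset=4.0, seed=3)
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    assert SimConfig.from_yaml(path) == cfg
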