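"""Shared fixtures: simulated cohorts and a trained segmenter.

The expensive fixtures are session-scoped so the cohort is rendered once
and the network trained once for all tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

from lithofocus.simulate import SimConfig, simulate_cohort
from lithofocus.training import TrainConfig, packets_to_arrays, train
from lithofocus.unet import UNet, UNetConfig


@pytest.fixture(scope="session")
def cohort11():
    """An 11-patient cohort at the study's frame budget (200 frames each)."""
    return simulate_cohort(11, 1.0, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-patient, 80-frame cohort for cheap structural tests."""
    base = SimConfig(duration=80 / 15.0)
    return simulate_cohort(5, 1.0, seed=3, base_config=base)


@pytest.fixture(scope="session")
def trained_segmenter(cohort11):
    """A U-Net trained on 57 annotated frames from nine patients.

    Returns (model, history, cohort, held_out_test_id); the validation
    patient and the test patient contribute no training frames.
    """
    ids = list(cohort11)
    rng = np.random.default_rng(0)
    train_pk = []
    for pid in ids[:9]:
        packets = cohort11[pid][1]
        take = rng.choice(len(packets), size=7 if pid in ids[:3] else 6, replace=False)
        train_pk += [packets[i] for i in take]
    train_pk = train_pk[:57]
    val_pk = [cohort11[ids[9]][1][i] for i in rng.choice(200, size=6, replace=False)]
    model = UNet(UNetConfig(), seed=0)
    model, history = train(
        model,
        packets_to_arrays(train_pk),
        packets_to_arrays(val_pk),
        TrainConfig(max_epochs=30, patience=5, seed=0),
    )
    return model, history, cohort11, ids[10]
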