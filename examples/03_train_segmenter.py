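"""Train the stone/kidney U-Net on a small simulated cohort.

Six patients, eight annotated frames each, leave-one-patient-out for
validation and test; early stopping keeps the epoch with the lowest
validation loss.  Takes a minute or two on one CPU core.
"""

import numpy as np

from lithofocus import (
    SimConfig,
    TrainConfig,
    UNet,
    UNetConfig,
    dice,
    make_cv_splits,
    packets_to_arrays,
    predict_mask,
    simulate_cohort,
    train,
)

cohort = simulate_cohort(6, per_patient_config_jitter=1.0, seed=0,
                         base_config=SimConfig(duration=80 / 15))
plan = make_cv_splits(list(cohort))
train_ids, val_id, test_id = plan.folds[0]

rng = np.random.default_rng(0)
train_pk = [cohort[p][1][i] for p in train_ids
            for i in rng.choice(80, 8, replace=False)]
val_pk = [cohort[val_id][1][i] for i in rng.choice(80, 8, replace=False)]

model = UNet(UNetConfig(), seed=0)
model, history = train(model, packets_to_arrays(train_pk),
                       packets_to_arrays(val_pk),
                       TrainConfig(max_epochs=30, patience=5, seed=0))

scores = [dice(predict_mask(model, p.image)[0], p.stone_mask)
          for p in cohort[test_id][1][::8]]
print(f"training frames:      {len(train_pk)} from patients {train_ids}")
print(f"epochs run:           {len(history)}")
print(f"best validation loss: {history.val_loss.min():.4f}")
print(f"test-patient Dice:    median {np.median(scores):.2f}")

# Dice measures mask overlap with the simulator's ground truth on a
# patient whose frames never influenced the weights.
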