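"""Training loop, patient-based cross-validation, and mask prediction.

The evaluation protocol is leave-one-patient-out in both directions:
each fold trains on the majority of patients, monitors the validation
loss on one held-out patient for early stopping, and reserves a second
held-out patient for testing — no frame from the test patient ever
influences the weights.  Early stopping returns the weights from the
epoch with the minimum validation loss, the optimal stopping point on
the validation curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import FramePacket
from .unet import UNet, UNetConfig, bce_with_logits, sigmoid

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "make_cv_splits",
    "packets_to_arrays",
    "train",
    "predict_mask",
    "dice",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 8
    #: Epochs of non-improving validation loss tolerated before stopping.
    patience: int = 5
    #: Per-channel positive-pixel weights (stone, kidney) in the loss;
    #: the stone weight offsets its tiny foreground fraction.
    pos_weight: Tuple[float, float] = (20.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("max_epochs, batch_size, learning_rate must be positive")
        if not 0 <= self.patience < self.max_epochs:
            raise ValueError("patience must satisfy 0 <= patience < max_epochs")


@dataclass(frozen=True)
class SplitPlan:
    """Patient-level cross-validation folds: (train_ids, val_id, test_id)."""

    folds: Tuple[Tuple[Tuple[str, ...], str, str], ...]


def make_cv_splits(patient_ids: Sequence[str]) -> SplitPlan:
    """Rotation split plan: one fold per patient.

    In fold i, patient i is the validation patient, patient i+1 (cyclic)
    is the test patient, and everyone else trains.  Each patient serves
    as validation exactly once and as test exactly once.
    """
    ids = list(patient_ids)
    if len(ids) < 3:
        raise ValueError("patient-based cross-validation needs >= 3 patients")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    n = len(ids)
    folds = []
    for i in range(n):
        val = ids[i]
        test = ids[(i + 1) % n]
        train = tuple(p for p in ids if p not in (val, test))
        folds.append((train, val, test))
    return SplitPlan(tuple(folds))


def packets_to_arrays(packets: Sequence[FramePacket]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack frames into (N,1,H,W) inputs in [0,1] and (N,2,H,W) targets."""
    x = np.stack([p.image for p in packets]).astype(np.float32)[:, None] / 255.0
    y = np.stack(
        [np.stack([p.stone_mask, p.kidney_mask]).astype(np.float32) for p in packets]
    )
    return x, y


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _epoch_loss(
    model: UNet, x: np.ndarray, y: np.ndarray, batch: int, pos_weight
) -> float:
    total = 0.0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i : i + batch])
        loss, _ = bce_with_logits(logits, y[i : i + batch], pos_weight)
        total += loss * len(x[i : i + batch])
    return total / len(x)


def train(
    model: UNet,
    train_data: Tuple[np.ndarray, np.ndarray],
    val_data: Tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> Tuple[UNet, pd.DataFrame]:
    """Train with Adam and early stopping on the validation loss.

    Returns the model carrying the weights of the epoch with minimum
    validation loss, plus a per-epoch loss history (columns ``epoch``,
    ``train_loss``, ``val_loss``).  Fully deterministic given
    ``config.seed``.
    """
    xt, yt = train_data
    xv, yv = val_data
    if len(xt) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), config.learning_rate)
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xt))
        train_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            model.zero_grad()
            logits = model.forward(xt[sel])
            loss, grad = bce_with_logits(logits, yt[sel], config.pos_weight)
            model.backward(grad)
            opt.step(model.gradients())
            train_loss += loss * len(sel)
        train_loss /= len(xt)
        val_loss = _epoch_loss(model, xv, yv, config.batch_size, config.pos_weight)
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    model.set_weights(best_weights)
    return model, pd.DataFrame(rows)


def predict_mask(
    model: UNet, frame: np.ndarray, threshold: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Predict binary stone and kidney masks for one grayscale frame.

    The frame is rescaled to the network's input size (bilinear) if
    needed and the predicted masks are mapped back to the frame's
    geometry with nearest-neighbour interpolation.
    """
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if frame.max() > 1.0:
        frame = frame / 255.0
    size = model.config.input_size
    h, w = frame.shape
    if (h, w) != (size, size):
        frame_in = ndimage.zoom(frame, (size / h, size / w), order=1)
    else:
        frame_in = frame
    proba = sigmoid(model.forward(frame_in[None, None]))[0]
    stone = proba[0] >= threshold
    kidney = proba[1] >= threshold
    if (h, w) != (size, size):
        stone = ndimage.zoom(stone, (h / size, w / size), order=0)
        kidney = ndimage.zoom(kidney, (h / size, w / size), order=0)
    return stone, kidney


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (pred & truth).sum() / float(denom)


def save_weights(model: UNet, path: str | Path) -> None:
    np.savez(path, *(p for p in model.parameters()))


def load_weights(model: UNet, path: str | Path) -> UNet:
    with np.load(path) as data:
        model.set_weights([data[k] for k in data.files])
    return model
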