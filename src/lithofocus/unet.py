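"""A small U-Net implemented directly on numpy.

The architecture is the canonical encoder–decoder segmenter: a
contracting path of 3×3 convolution + ReLU pairs with 2×2 maximum
pooling, a bottleneck, and an expanding path of 2× upsampling stages
whose feature maps are concatenated with the symmetric encoder features
(the crossover/skip connections that preserve high-resolution detail).
The head is a 1×1 convolution to two independent sigmoid channels —
stone and kidney — rather than mutually exclusive classes, because the
stone lies inside the kidney and both masks can be true for one pixel.

Everything (im2col convolutions, pooling, backprop, Adam) is written on
numpy arrays: the networks used here are tiny (tens of thousands of
parameters at 64×64 input) and train to convergence in seconds on one
CPU core, which keeps the whole pipeline runnable without a GPU stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNetConfig", "UNet", "bce_with_logits", "sigmoid"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling stages; the bottleneck feature map
    is ``input_size / 2**depth`` on a side, so ``input_size`` must be
    divisible by ``2**depth``.
    """

    depth: int = 3
    base_channels: int = 8
    in_channels: int = 1
    out_channels: int = 2
    input_size: int = 64

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError("input_size must be divisible by 2**depth")
        if min(self.base_channels, self.in_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: np.ndarray | None = None
) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all pixels/channels, with gradient.

    ``pos_weight`` (one value per channel) up-weights positive pixels; it
    compensates for extreme foreground/background imbalance — a stone
    covers only ~1% of a frame, so the unweighted loss is minimized by
    predicting no stone at all.
    """
    z, t = logits, targets
    softplus = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if pos_weight is None:
        loss = softplus
        grad = (sigmoid(z) - t) / z.size
    else:
        pw = np.asarray(pos_weight, dtype=z.dtype).reshape(1, -1, 1, 1)
        w = 1.0 + (pw - 1.0) * t
        loss = w * softplus
        grad = w * (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad


class _Conv:
    """3×3 (same-padded) or 1×1 convolution with He-initialized weights."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.k = k
        self.pad = k // 2
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: Tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        f = self.w.shape[0]
        y = cols @ self.w.reshape(f, -1).T + self.b
        self._cols, self._xshape = cols, x.shape
        return y.reshape(n, h, w, f).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        f = self.w.shape[0]
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, f)
        self.dw += (dyf.T @ self._cols).reshape(self.w.shape)
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.w.reshape(f, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _maxpool2(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool2_backward(dy: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    n, c, h, w = in_shape
    flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
    return (
        flat.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Encoder–decoder segmenter with skip concatenations.

    Channel widths double at each pooling stage starting from
    ``base_channels``; the decoder mirrors the encoder.  ``forward``
    caches activations for ``backward``, which accumulates parameter
    gradients (call :meth:`zero_grad` between steps).
    """

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, c0 = config.depth, config.base_channels
        ch = [c0 * 2**i for i in range(d + 1)]

        self.enc: List[Tuple[_Conv, _ReLU, _Conv, _ReLU]] = []
        c_in = config.in_channels
        for i in range(d):
            self.enc.append(
                (_Conv(c_in, ch[i], 3, rng), _ReLU(), _Conv(ch[i], ch[i], 3, rng), _ReLU())
            )
            c_in = ch[i]
        self.bottleneck = (
            _Conv(ch[d - 1], ch[d], 3, rng),
            _ReLU(),
            _Conv(ch[d], ch[d], 3, rng),
            _ReLU(),
        )
        self.dec: List[Tuple[_Conv, _ReLU, _Conv, _ReLU, _Conv, _ReLU]] = []
        for i in reversed(range(d)):
            # up-conv after nearest upsampling, then two convs on the
            # concatenation [skip, up] with 2*ch[i] input channels.
            self.dec.append(
                (
                    _Conv(ch[i + 1], ch[i], 3, rng),
                    _ReLU(),
                    _Conv(2 * ch[i], ch[i], 3, rng),
                    _ReLU(),
                    _Conv(ch[i], ch[i], 3, rng),
                    _ReLU(),
                )
            )
        self.head = _Conv(c0, config.out_channels, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _convs(self) -> List[_Conv]:
        convs: List[_Conv] = []
        for blk in self.enc:
            convs += [blk[0], blk[2]]
        convs += [self.bottleneck[0], self.bottleneck[2]]
        for blk in self.dec:
            convs += [blk[0], blk[2], blk[4]]
        convs.append(self.head)
        return convs

    def parameters(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for conv in self._convs():
            out += [conv.w, conv.b]
        return out

    def gradients(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for conv in self._convs():
            out += [conv.dw, conv.db]
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: List[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Compute per-pixel logits of shape (N, out_channels, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}×{self.config.input_size} input"
            )
        self._skips = []
        self._pool = []
        h = x
        for c1, r1, c2, r2 in self.enc:
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
            self._skips.append(h)
            h, idx = _maxpool2(h)
            self._pool.append((idx, self._skips[-1].shape))
        c1, r1, c2, r2 = self.bottleneck
        h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        self._cat_split = []
        for blk, skip in zip(self.dec, reversed(self._skips)):
            uc, ur, c1, r1, c2, r2 = blk
            h = ur.forward(uc.forward(_upsample2(h)))
            self._cat_split.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dskips: List[np.ndarray] = []
        for blk, n_skip in zip(reversed(self.dec), reversed(self._cat_split)):
            uc, ur, c1, r1, c2, r2 = blk
            d = c1.backward(r1.backward(c2.backward(r2.backward(dh))))
            dskips.append(d[:, :n_skip])
            dh = _upsample2_backward(uc.backward(ur.backward(d[:, n_skip:])))
        c1, r1, c2, r2 = self.bottleneck
        dh = c1.backward(r1.backward(c2.backward(r2.backward(dh))))
        for blk, (idx, shape), dskip in zip(
            reversed(self.enc), reversed(self._pool), reversed(dskips)
        ):
            c1, r1, c2, r2 = blk
            d = _maxpool2_backward(dh, idx, shape) + dskip
            dh = c1.backward(r1.backward(c2.backward(r2.backward(d))))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel channel probabilities (no gradient caches kept)."""
        return sigmoid(self.forward(x))
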