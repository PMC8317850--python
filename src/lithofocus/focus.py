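"""Focal-zone overlap gating.

A lithotripter concentrates shockwave energy in a fixed focal zone (FZ).
A frame is a firing opportunity ("in focus") when at least half of the
stone's cross-section lies inside the FZ; firing on any other frame is a
mishit that deposits energy in surrounding tissue.  This module converts a
binary stone mask into that firing decision by exact pixel counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FocalZone",
    "FocusCall",
    "IN_FOCUS",
    "OUT_OF_FOCUS",
    "NO_DETECTION",
    "MIN_DETECTION_PIXELS",
    "overlap_fraction",
    "classify_frame",
    "apply_no_detection_policy",
]

IN_FOCUS = "in_focus"
OUT_OF_FOCUS = "out_of_focus"
NO_DETECTION = "no_detection"

#: Predicted masks smaller than this many pixels are treated as "no stone
#: detected": a region that small is indistinguishable from speckle noise.
MIN_DETECTION_PIXELS = 5


@dataclass(frozen=True)
class FocalZone:
    """Fixed focal-zone geometry in image pixel coordinates.

    Parameters
    ----------
    center : (x, y)
        Zone centre; x is the column index, y the row index.
    semi_axes : (a, b)
        Semi-axes in pixels; a along x, b along y.
    shape : {"ellipse", "rectangle"}
        Geometric model of the zone. Piezoelectric focal zones are
        ellipsoidal, so "ellipse" is the default.
    """

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    shape: Literal["ellipse", "rectangle"] = "ellipse"

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("focal-zone semi-axes must be positive")
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown focal-zone shape {self.shape!r}")

    def mask(self, image_shape: Tuple[int, int]) -> np.ndarray:
        """Rasterize the zone onto a (height, width) grid as a bool mask."""
        h, w = image_shape
        cx, cy = self.center
        a, b = self.semi_axes
        yy, xx = np.ogrid[:h, :w]
        if self.shape == "ellipse":
            inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        else:
            inside = (np.abs(xx - cx) <= a) & (np.abs(yy - cy) <= b)
        return inside


@dataclass(frozen=True)
class FocusCall:
    """The per-frame gating decision with its supporting overlap fraction.

    ``overlap`` is None for no-detection frames, where no fraction exists.
    """

    value: str
    overlap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value not in (IN_FOCUS, OUT_OF_FOCUS, NO_DETECTION):
            raise ValueError(f"unknown focus call {self.value!r}")


def overlap_fraction(stone_mask: np.ndarray, zone: FocalZone) -> float:
    """Fraction of the stone's pixels lying inside the focal zone.

    Computed by exact pixel counting: |stone ∩ zone| / |stone|.
    """
    stone = np.asarray(stone_mask, dtype=bool)
    n_stone = int(stone.sum())
    if n_stone == 0:
        raise ValueError("overlap_fraction is undefined for an empty mask")
    inside = zone.mask(stone.shape)
    return float((stone & inside).sum()) / n_stone


def classify_frame(
    stone_mask: np.ndarray,
    zone: FocalZone,
    threshold: float = 0.5,
    min_pixels: int = MIN_DETECTION_PIXELS,
) -> FocusCall:
    """Turn a predicted stone mask into a firing decision.

    The decision is *in focus* when the overlap fraction is greater than or
    equal to ``threshold`` — the boundary case counts as a hit.  Masks with
    fewer than ``min_pixels`` pixels produce a *no detection* call; the
    downstream policy decides how those frames enter the analysis.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    stone = np.asarray(stone_mask, dtype=bool)
    if int(stone.sum()) < min_pixels:
        return FocusCall(NO_DETECTION)
    frac = overlap_fraction(stone, zone)
    return FocusCall(IN_FOCUS if frac >= threshold else OUT_OF_FOCUS, frac)


def apply_no_detection_policy(
    calls: Sequence[FocusCall] | Iterable[FocusCall],
    policy: Literal["exclude", "as_out_of_focus"] = "exclude",
) -> Tuple[List[int], List[int], int]:
    """Resolve no-detection frames before confusion-matrix construction.

    Two policies are supported:

    - ``"exclude"`` drops no-detection frames from the evaluation entirely
      (they are counted but contribute nothing);
    - ``"as_out_of_focus"`` relabels them as out-of-focus, the conservative
      reading that an undetected stone must not be fired upon.

    Returns
    -------
    decisions : list of int
        Binary decisions (1 = in focus) for the retained frames, in input
        order.
    kept_indices : list of int
        Positions of the retained frames within ``calls``.
    n_excluded : int
        Number of no-detection frames dropped (zero for the relabel policy).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no focus calls supplied")
    if policy not in ("exclude", "as_out_of_focus"):
        raise ValueError(f"unknown no-detection policy {policy!r}")
    decisions: List[int] = []
    kept: List[int] = []
    n_excluded = 0
    for i, call in enumerate(calls):
        if call.value == NO_DETECTION:
            if policy == "exclude":
                n_excluded += 1
                continue
            decisions.append(0)
        else:
            decisions.append(1 if call.value == IN_FOCUS else 0)
        kept.append(i)
    return decisions, kept, n_excluded
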