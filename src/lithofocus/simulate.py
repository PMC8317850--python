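"""Synthetic B-mode-like ultrasound sequences of a respirating kidney stone.

The study system is a kidney stone imaged by an inline ultrasound probe
during shockwave lithotripsy.  Respiration carries the stone along a
roughly linear path in the imaging plane; the motion dwells at the end of
expiration, where the stone is nearly stationary and — when the operator
has centred the crosshair well — sits inside the lithotripter's focal
zone.  The generator emulates exactly the features the downstream stages
need: a speckled kidney region, a bright elliptical stone echo with an
acoustic shadow beneath it, a fixed focal-zone geometry, and per-frame
ground-truth masks and in/out-of-focus labels derived by exact pixel
counting.  It makes no attempt at RF-level acoustic physics.

Motion model: a 1-D periodic displacement s(t) = A·sin^(2p)(πt/T) mapped
onto a line in the image plane.  The exponent p ≥ 1 flattens the minima,
producing the end-expiration dwell with a single parameter; p = 1 gives
ordinary raised-cosine motion, large p a stone that is stationary except
for brief transits.  An offset shifts the dwell position relative to the
focal-zone centre, which is what makes per-patient hit rates range from
poor to excellent in a simulated cohort.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import yaml

from .annotations import FrameLabels
from .focus import IN_FOCUS, OUT_OF_FOCUS, FocalZone

__all__ = [
    "SimConfig",
    "MotionTrajectory",
    "FramePacket",
    "respiratory_trajectory",
    "render_frame",
    "generate_sequence",
    "simulate_cohort",
    "write_sequence_png",
]


def _default_focal_zone() -> FocalZone:
    return FocalZone(center=(32.0, 28.0), semi_axes=(7.0, 9.0))


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated patient sequence.

    Geometry is in pixels on a row-major grid with the origin at the top
    left; positions are (x, y) with x the column.  Intensities are 8-bit
    gray levels.  Defaults produce a 64×64 sequence at 15 frames/s whose
    stone dwells inside the focal zone at end-expiration, i.e. a
    well-centred treatment.
    """

    image_height: int = 64
    image_width: int = 64
    frame_rate: float = 15.0
    duration: float = 200 / 15.0
    respiratory_period: float = 4.0
    dwell_exponent: float = 2.0
    motion_amplitude: float = 22.0
    #: Direction of the respiratory line in the image plane (x, y);
    #: normalized internally.  Mostly cranio-caudal, i.e. along y.
    motion_direction: Tuple[float, float] = (0.2, 1.0)
    #: Displacement (pixels, along the motion line) of the end-expiration
    #: dwell point from the focal-zone centre.  0 = perfectly targeted.
    dwell_offset: float = 0.0
    phase: float = 0.0
    stone_axes: Tuple[float, float] = (4.0, 3.0)
    stone_intensity: float = 230.0
    background_intensity: float = 40.0
    kidney_intensity: float = 95.0
    speckle_shape: float = 6.0
    shadow_strength: float = 0.5
    shadow_length: float = 15.0
    kidney_axes: Tuple[float, float] = (24.0, 27.0)
    kidney_center: Tuple[float, float] = (32.0, 33.0)
    focal_zone: FocalZone = field(default_factory=_default_focal_zone)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.respiratory_period <= 0:
            raise ValueError("respiratory_period must be positive")
        if self.motion_amplitude <= 0:
            raise ValueError("motion_amplitude must be positive")
        if self.dwell_exponent < 1:
            raise ValueError("dwell_exponent must be >= 1")
        if min(self.stone_axes) <= 0 or min(self.kidney_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        # The stone must remain inside the image over the whole trajectory.
        a, b = self.stone_axes
        for s in (0.0, self.motion_amplitude):
            x, y = self._position_at_displacement(s)
            if not (a <= x <= self.image_width - 1 - a and b <= y <= self.image_height - 1 - b):
                raise ValueError(
                    "stone trajectory leaves the image: reduce motion_amplitude "
                    "or dwell_offset"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    @property
    def _unit_direction(self) -> Tuple[float, float]:
        dx, dy = self.motion_direction
        norm = float(np.hypot(dx, dy))
        if norm == 0:
            raise ValueError("motion_direction must be non-zero")
        return dx / norm, dy / norm

    def _position_at_displacement(self, s: float) -> Tuple[float, float]:
        ux, uy = self._unit_direction
        cx, cy = self.focal_zone.center
        return cx + ux * (s - self.dwell_offset), cy + uy * (s - self.dwell_offset)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "focal_zone"
        }
        fz = self.focal_zone
        d["focal_zone"] = {
            "center": list(fz.center),
            "semi_axes": list(fz.semi_axes),
            "shape": fz.shape,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        fz = d.pop("focal_zone")
        for key in ("motion_direction", "stone_axes", "kidney_axes", "kidney_center"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(
            focal_zone=FocalZone(
                center=tuple(fz["center"]),
                semi_axes=tuple(fz["semi_axes"]),
                shape=fz.get("shape", "ellipse"),
            ),
            **d,
        )


@dataclass(frozen=True)
class MotionTrajectory:
    """Stone-centre (x, y) coordinates, one entry per frame."""

    positions: np.ndarray  # (n_frames, 2) float

    def __len__(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class FramePacket:
    """One simulated frame with its ground truth.

    ``true_overlap`` is the exact pixel-count fraction of the stone inside
    the focal zone and ``true_label`` applies the ≥50% rule to it.
    """

    image: np.ndarray  # (H, W) uint8
    stone_mask: np.ndarray  # (H, W) bool
    kidney_mask: np.ndarray  # (H, W) bool
    true_overlap: float
    true_label: str

    @property
    def label_int(self) -> int:
        return 1 if self.true_label == IN_FOCUS else 0


def respiratory_trajectory(config: SimConfig) -> MotionTrajectory:
    """Deterministic periodic stone path with an end-expiration dwell.

    The displacement along the motion line is A·sin^(2p)(π(t/T + φ)); the
    flat minima of the even sine power are the end-expiration dwells.
    """
    n = config.n_frames
    t = np.arange(n) / config.frame_rate
    u = np.abs(np.sin(np.pi * (t / config.respiratory_period + config.phase)))
    s = config.motion_amplitude * u ** (2 * config.dwell_exponent)
    ux, uy = config._unit_direction
    cx, cy = config.focal_zone.center
    pos = np.empty((n, 2))
    pos[:, 0] = cx + ux * (s - config.dwell_offset)
    pos[:, 1] = cy + uy * (s - config.dwell_offset)
    return MotionTrajectory(pos)


def _ellipse_mask(
    shape: Tuple[int, int], center: Tuple[float, float], axes: Tuple[float, float]
) -> np.ndarray:
    h, w = shape
    cx, cy = center
    a, b = axes
    yy, xx = np.ogrid[:h, :w]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    # A per-frame stream keyed on (seed, frame) so any frame can be
    # rendered independently yet reproducibly.
    return np.random.default_rng([seed & 0x7FFFFFFF, frame_index])


def render_frame(
    trajectory: MotionTrajectory, frame_index: int, config: SimConfig
) -> FramePacket:
    """Render one frame: speckled kidney, bright stone echo, acoustic shadow.

    The image is a piecewise-smooth intensity map (background, kidney,
    stone) degraded by multiplicative gamma-distributed speckle of unit
    mean, the standard first-order B-mode speckle emulation.  The column
    band beneath the stone is attenuated to imitate the acoustic shadow a
    calcified stone casts.
    """
    if not 0 <= frame_index < len(trajectory):
        raise IndexError("frame_index outside trajectory")
    h, w = config.image_height, config.image_width
    cx, cy = trajectory.positions[frame_index]
    a, b = config.stone_axes
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("stone centre outside image bounds")

    kidney = _ellipse_mask((h, w), config.kidney_center, config.kidney_axes)
    stone = _ellipse_mask((h, w), (cx, cy), (a, b))
    if not stone.any():
        raise ValueError("rendered stone mask is empty")

    base = np.full((h, w), config.background_intensity, dtype=float)
    base[kidney] = config.kidney_intensity

    # Acoustic shadow: attenuate below the stone in its column band.
    yy = np.arange(h)[:, None]
    cols = stone.any(axis=0)[None, :]
    depth = yy - (cy + b)
    atten = np.where(
        cols & (depth > 0),
        1.0 - config.shadow_strength * np.exp(-depth / config.shadow_length),
        1.0,
    )
    base *= atten
    base[stone] = config.stone_intensity

    rng = _frame_rng(config.seed, frame_index)
    k = config.speckle_shape
    speckle = rng.gamma(k, 1.0 / k, size=(h, w))
    image = np.clip(base * speckle, 0, 255).astype(np.uint8)

    fz = config.focal_zone.mask((h, w))
    overlap = float((stone & fz).sum()) / float(stone.sum())
    label = IN_FOCUS if overlap >= 0.5 else OUT_OF_FOCUS
    return FramePacket(image, stone, kidney, overlap, label)


def generate_sequence(
    config: SimConfig, patient_id: str = "sim"
) -> Tuple[List[FramePacket], FrameLabels]:
    """Render a full sequence and its ground-truth label track."""
    traj = respiratory_trajectory(config)
    packets = [render_frame(traj, i, config) for i in range(len(traj))]
    labels = FrameLabels(
        np.array([p.label_int for p in packets], dtype=np.int8), patient_id
    )
    return packets, labels


def _spawn_seed(seed: int, i: int) -> int:
    h = hashlib.sha256(f"{seed}:{i}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def simulate_cohort(
    n_patients: int,
    per_patient_config_jitter: float = 1.0,
    seed: int = 0,
    base_config: SimConfig | None = None,
) -> Dict[str, Tuple[SimConfig, List[FramePacket], FrameLabels]]:
    """Simulate a cohort of patients with heterogeneous targeting quality.

    ``per_patient_config_jitter`` in [0, 1] scales how much stone size,
    respiratory amplitude, phase and — decisively for the hit rate — the
    dwell-point offset from the focal-zone centre vary across patients.
    At jitter 0 every patient shares one configuration (identical label
    tracks, a perfectly homogeneous cohort); at jitter 1 hit rates spread
    over roughly 15–95%, the heterogeneity seen across real treatments
    where some stones sit in the focal zone most of the cycle and others
    only transit it.
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients for train/val/test splits")
    if not 0.0 <= per_patient_config_jitter <= 1.0:
        raise ValueError("jitter must lie in [0, 1]")
    base = base_config or SimConfig()
    j = per_patient_config_jitter
    rng = np.random.default_rng(seed)
    cohort: Dict[str, Tuple[SimConfig, List[FramePacket], FrameLabels]] = {}
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        amp = base.motion_amplitude * (1.0 + j * rng.uniform(-0.35, 0.35))
        offset = j * rng.uniform(0.0, 16.0)
        scale = 1.0 + j * rng.uniform(-0.25, 0.25)
        cfg = replace(
            base,
            motion_amplitude=float(amp),
            dwell_offset=float(offset),
            phase=float(j * rng.uniform(0, 1)),
            dwell_exponent=float(base.dwell_exponent + j * rng.uniform(-0.5, 1.5)),
            stone_axes=(base.stone_axes[0] * scale, base.stone_axes[1] * scale),
            seed=_spawn_seed(seed, i),
        )
        packets, labels = generate_sequence(cfg, pid)
        cohort[pid] = (cfg, packets, labels)
    return cohort


def write_sequence_png(
    packets: List[FramePacket], out_dir: str | Path, patient_id: str = "sim"
) -> None:
    """Write frames and masks as 8-bit grayscale PNGs, one file per frame."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(packets):
        stem = f"{patient_id}_{i:05d}"
        iio.imwrite(out / f"{stem}.png", p.image)
        iio.imwrite(out / f"{stem}_stone.png", (p.stone_mask * 255).astype(np.uint8))
        iio.imwrite(out / f"{stem}_kidney.png", (p.kidney_mask * 255).astype(np.uint8))
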