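"""Salt-and-pepper noise injection with ground truth, and phantom images.

The simulator corrupts an 8-bit RGB image by flipping samples to the extreme
intensities 0 (pepper) or 255 (salt) and records exactly which samples were
touched, so detector precision/recall can be measured against ground truth.
Two counting modes are supported:

* ``monochrome`` (default) — one Bernoulli draw per *pixel*; a corrupted
  pixel gets the same impulse value on all three channels.  This matches
  gray sources such as chest X-rays.
* ``channelwise`` — independent draws per channel sample, the conventional
  model for color images.

Phantoms are piecewise-smooth synthetic scenes standing in for the usual
256x256 test photographs: flat plates, linear ramps, constant blocks with
strong step edges, and a stylized chest radiograph (gradient background,
two dark lung fields, bright rib arcs).  Clean phantom intensities are kept
inside [45, 210]: an impulse is only detectable while its contrast against
the scene exceeds the detector's response floor (threshold / center weight),
and mid-gray scenes keep both salt and pepper impulses above that floor —
the regime the method is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NoiseSpec",
    "CorruptionRecord",
    "add_salt_pepper",
    "make_phantom",
    "plant_collision",
    "PHANTOM_KINDS",
]

PHANTOM_KINDS = ("flat", "gradient", "blocks", "chest_like")


@dataclass(frozen=True)
class NoiseSpec:
    """Impulse-noise parameters.

    percentage : fraction of corrupted pixels (monochrome) or samples
        (channelwise), in percent, 0-100.
    salt_fraction : share of impulses set to 255; the rest become 0.
    mode : "monochrome" or "channelwise".
    seed : RNG seed; identical spec+seed reproduces the corruption exactly.
    """

    percentage: float
    salt_fraction: float = 0.5
    mode: str = "monochrome"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentage <= 100.0:
            raise ValueError(f"noise percentage must be in [0, 100], got {self.percentage}")
        if not 0.0 <= self.salt_fraction <= 1.0:
            raise ValueError(f"salt_fraction must be in [0, 1], got {self.salt_fraction}")
        if self.mode not in ("monochrome", "channelwise"):
            raise ValueError(f"unknown noise mode {self.mode!r}")


@dataclass(frozen=True)
class CorruptionRecord:
    """A noisy image together with its ground-truth corruption masks."""

    noisy: np.ndarray  # HxWx3 uint8
    truth_mask: np.ndarray  # HxW bool: pixel corrupted in >= 1 channel
    per_channel_mask: np.ndarray  # HxWx3 bool

    @property
    def corrupted_pixel_count(self) -> int:
        return int(self.truth_mask.sum())


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError(f"expected a nonempty HxWx3 image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 samples, got {image.dtype}")
    return image


def add_salt_pepper(image: np.ndarray, spec: NoiseSpec) -> CorruptionRecord:
    """Corrupt ``image`` per ``spec``; unflagged samples stay byte-identical.

    Each pixel (monochrome) or channel sample (channelwise) is independently
    corrupted with probability ``percentage/100``; a corrupted sample becomes
    255 with probability ``salt_fraction``, else 0.  Samples whose drawn
    impulse equals the clean value are still counted as corrupted (the mask
    marks the pixel if any channel actually changed; for phantoms inside
    [45, 210] every impulse changes the value).
    """
    image = _as_rgb(image)
    rng = np.random.default_rng(spec.seed)
    p = spec.percentage / 100.0
    h, w, _ = image.shape
    noisy = image.copy()

    if spec.mode == "monochrome":
        hit = rng.random((h, w)) < p
        salt = rng.random((h, w)) < spec.salt_fraction
        value = np.where(salt, 255, 0).astype(np.uint8)
        noisy[hit] = value[hit, None]
        per_channel = np.repeat(hit[:, :, None], 3, axis=2)
    else:
        hit = rng.random((h, w, 3)) < p
        salt = rng.random((h, w, 3)) < spec.salt_fraction
        value = np.where(salt, 255, 0).astype(np.uint8)
        noisy[hit] = value[hit]
        per_channel = hit

    per_channel = per_channel & (noisy != image)
    truth = per_channel.any(axis=2)
    return CorruptionRecord(noisy=noisy, truth_mask=truth, per_channel_mask=per_channel)


def plant_collision(
    image: np.ndarray, positions: Sequence[tuple[int, int]], value: int
) -> CorruptionRecord:
    """Force the listed pixels (all channels) to an impulse value.

    Used to build deterministic "collision" fixtures: 4-/8-connected groups
    of same-valued impulses that hide each other from neighbor-based
    detectors.
    """
    image = _as_rgb(image)
    if value not in (0, 255):
        raise ValueError(f"impulse value must be 0 or 255, got {value}")
    h, w, _ = image.shape
    noisy = image.copy()
    truth = np.zeros((h, w), dtype=bool)
    for r, c in positions:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"position ({r}, {c}) outside a {h}x{w} image")
        noisy[r, c] = value
        truth[r, c] = True
    per_channel = np.repeat(truth[:, :, None], 3, axis=2) & (noisy != image)
    return CorruptionRecord(noisy=noisy, truth_mask=truth, per_channel_mask=per_channel)


def _gray(level: np.ndarray | float, h: int, w: int) -> np.ndarray:
    plane = np.broadcast_to(np.asarray(level, dtype=np.float64), (h, w))
    plane = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
    return np.repeat(plane[:, :, None], 3, axis=2)


def make_phantom(kind: str, height: int, width: int, seed: int = 0) -> np.ndarray:
    """Deterministic piecewise-smooth 8-bit RGB phantom.

    kinds:
      flat        one constant mid-gray plate
      gradient    a smooth diagonal ramp (affine, hence invisible to the
                  zero-sum kernel banks)
      blocks      four constant quadrants, adjacent steps >= 60 levels
      chest_like  gradient background, two dark elliptical lung fields,
                  bright rib-like arcs
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; expected one of {PHANTOM_KINDS}")
    if height < 16 or width < 16:
        raise ValueError(f"phantom must be at least 16x16, got {height}x{width}")
    rng = np.random.default_rng(seed)

    if kind == "flat":
        level = int(rng.integers(60, 196))  # mid-gray, well inside [45, 210]
        return _gray(float(level), height, width)

    rows = np.arange(height, dtype=np.float64)[:, None]
    cols = np.arange(width, dtype=np.float64)[None, :]

    if kind == "gradient":
        lo, hi = 50.0, 205.0
        t = (rows / max(height - 1, 1) + cols / max(width - 1, 1)) / 2.0
        return _gray(lo + (hi - lo) * t, height, width)

    if kind == "blocks":
        # 105 and 150 differ by only 45, so they sit on a diagonal; every
        # edge-sharing quadrant pair then steps by >= 60 intensity levels.
        layout = np.array([[105.0, 45.0], [210.0, 150.0]])
        # seed varies the placement via symmetries that preserve adjacency
        layout = np.rot90(layout, k=int(rng.integers(4)))
        if rng.integers(2):
            layout = layout.T
        plane = np.empty((height, width), dtype=np.float64)
        hm, wm = height // 2, width // 2
        plane[:hm, :wm] = layout[0, 0]
        plane[:hm, wm:] = layout[0, 1]
        plane[hm:, :wm] = layout[1, 0]
        plane[hm:, wm:] = layout[1, 1]
        return _gray(plane, height, width)

    # chest_like
    lo, hi = 90.0, 150.0
    plane = lo + (hi - lo) * (rows / max(height - 1, 1)) * np.ones_like(cols)
    cy, cx = height / 2.0, width / 2.0
    ry, rx = height * 0.30, width * 0.18
    jitter = rng.uniform(-0.02, 0.02, size=4)  # mild anatomical variation
    for side in (-1.0, 1.0):
        lung_cx = cx + side * width * (0.22 + jitter[0 if side < 0 else 1])
        lung_cy = cy * (1.0 + jitter[2])
        d = ((rows - lung_cy) / ry) ** 2 + ((cols - lung_cx) / rx) ** 2
        plane = np.where(d <= 1.0, 55.0, plane)
    # rib arcs: bright sinusoidal bands across the thorax
    phase = 2.0 * np.pi * (rows / max(height / 6.0, 1.0)) + jitter[3]
    band = (np.sin(phase + 0.3 * np.sin(2 * np.pi * cols / max(width, 1))) > 0.93)
    thorax = (np.abs(cols - cx) < width * 0.45) & (np.abs(rows - cy) < height * 0.42)
    plane = np.where(band & thorax, np.minimum(plane + 70.0, 205.0), plane)
    plane = np.clip(plane, 45.0, 210.0)
    return _gray(plane, height, width)
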