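"""Directional Laplacian kernel banks for impulse-noise detection.

Impulse ("salt and pepper") noise flips isolated pixels to 0 or 255.  A
zero-sum second-derivative stencil responds strongly to such an outlier and
not at all to constant (or affine) surroundings, which makes banks of
directional Laplacian stencils natural impulse detectors: a pixel is
impulse-like only if *every* direction shows a strong variation, so the
detector thresholds the minimum response over the bank.

Two banks of 5x5 integer stencils are built here:

* **First round, K1-K8** — one kernel per direction in steps of pi/8
  (K1 at 0, K2 at pi/4, K3 at pi/2, K4 at 3pi/4, then K5-K8 at the
  intermediate pi/8-family angles).  Each places unit negative weights on
  the ring-1 and ring-2 lattice cells closest in angle to its direction
  (plus their point mirrors) and a center weight of +4.
* **Second round, K9-K16** — the same eight directions, but the negative
  weights live only on the outer ring at Chebyshev distance 2 and the
  eight direct neighbors of the center carry exactly 0.  Center weight +2.
  These kernels ignore the direct neighborhood entirely, so an impulse
  whose direct neighbors are corrupted at the same value (a "collision")
  is still seen against the clean outer ring.

Weights are kept as exact signed integers with a positive center; responses
are compared against an absolute threshold (default 75), so any rescaling of
the weights must rescale the threshold identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np

__all__ = [
    "Round",
    "Kernel",
    "KernelBank",
    "build_kernel_bank",
    "reference_laplacian_3x3",
    "kernel_bank_checksum",
]

KERNEL_SIZE = 5
_C = KERNEL_SIZE // 2  # center offset

#: The eight nominal directions, in radians, indexed 0..7.
ANGLES = tuple(k * math.pi / 8 for k in range(8))

# id -> angle assignment for the first round follows the published naming:
# K1..K4 are the classic pi/4-step kernels, K5..K8 fill in the pi/8 family.
_FIRST_ROUND_ANGLE = {
    "K1": 0.0,
    "K2": math.pi / 4,
    "K3": math.pi / 2,
    "K4": 3 * math.pi / 4,
    "K5": math.pi / 8,
    "K6": 3 * math.pi / 8,
    "K7": 5 * math.pi / 8,
    "K8": 7 * math.pi / 8,
}
# Second-round ids ascend with angle.
_SECOND_ROUND_ANGLE = {f"K{9 + k}": ANGLES[k] for k in range(8)}


class Round(str, Enum):
    """Which detection pass a kernel belongs to."""

    first = "first"
    second = "second"


@dataclass(frozen=True)
class Kernel:
    """A 5x5 signed-integer directional Laplacian stencil.

    Attributes
    ----------
    id : str
        Identity ``K1``..``K16``.
    weights : numpy.ndarray
        5x5 int array; sums to zero, positive center, negative off-center.
    round : Round
        ``first`` (K1-K8) or ``second`` (K9-K16).
    angle : float
        Nominal direction in radians, a multiple of pi/8.
    """

    id: str
    weights: np.ndarray
    round: Round
    angle: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.shape != (KERNEL_SIZE, KERNEL_SIZE):
            raise ValueError(f"kernel {self.id}: weights must be 5x5, got {w.shape}")
        object.__setattr__(self, "weights", w)
        w.setflags(write=False)

    def __str__(self) -> str:  # pretty stencil for the CLI
        rows = ["  ".join(f"{v:3d}" for v in row) for row in self.weights]
        return f"{self.id} ({self.round.value} round, {self.angle / math.pi:.3f}*pi)\n" + "\n".join(rows)


def _ring_cells(radius: int) -> list[tuple[int, int]]:
    """Lattice cells at Chebyshev distance ``radius`` from the origin."""
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if max(abs(dr), abs(dc)) == radius
    ]


def _nearest_ring_cell(theta: float, radius: int) -> tuple[int, int]:
    """Ring cell whose direction (mod pi) is angularly closest to ``theta``.

    Ties (the pi/8-family angles fall exactly between two ring-1 cells) break
    toward the candidate angularly just below ``theta``; that offset is
    preserved by rotation, so both banks stay closed under 90-degree rotation.
    """
    theta = theta % math.pi
    best: tuple[tuple[float, float], tuple[int, int]] | None = None
    for dr, dc in _ring_cells(radius):
        ang = math.atan2(dr, dc) % math.pi
        dist = abs(ang - theta)
        dist = min(dist, math.pi - dist)
        below = (theta - ang) % math.pi  # 0 when aligned, small when just below
        key = (round(dist, 12), round(below, 12))
        if best is None or key < best[0]:
            best = (key, (dr, dc))
    assert best is not None
    return best[1]


def _directional_weights(theta: float, radii: tuple[int, ...]) -> np.ndarray:
    """Zero-sum stencil: -1 at the ring cells (and mirrors) along ``theta``."""
    w = np.zeros((KERNEL_SIZE, KERNEL_SIZE), dtype=np.int64)
    for radius in radii:
        dr, dc = _nearest_ring_cell(theta, radius)
        w[_C + dr, _C + dc] = -1
        w[_C - dr, _C - dc] = -1
    w[_C, _C] = -w.sum()
    return w


@dataclass(frozen=True)
class KernelBank:
    """The ordered bank K1..K16 (8 first-round + 8 second-round kernels)."""

    kernels: tuple[Kernel, ...]

    def __iter__(self) -> Iterator[Kernel]:
        return iter(self.kernels)

    def __len__(self) -> int:
        return len(self.kernels)

    def __getitem__(self, kernel_id: str) -> Kernel:
        for k in self.kernels:
            if k.id == kernel_id:
                return k
        raise KeyError(kernel_id)

    def round_kernels(self, which: Round | str) -> tuple[Kernel, ...]:
        """The 8 kernels of one round, in id order (stable argmin order)."""
        which = Round(which)
        return tuple(k for k in self.kernels if k.round is which)

    def to_dict(self) -> dict:
        """JSON-ready dump so the exact weights can be inspected/diffed."""
        return {
            k.id: {
                "round": k.round.value,
                "angle_over_pi": round(k.angle / math.pi, 6),
                "weights": k.weights.tolist(),
            }
            for k in self.kernels
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_kernel_bank() -> KernelBank:
    """Construct the 16-kernel bank. Deterministic: same weights every call."""
    kernels = []
    for kid, theta in _FIRST_ROUND_ANGLE.items():
        kernels.append(
            Kernel(kid, _directional_weights(theta, (1, 2)), Round.first, theta)
        )
    for kid, theta in _SECOND_ROUND_ANGLE.items():
        kernels.append(
            Kernel(kid, _directional_weights(theta, (2,)), Round.second, theta)
        )
    # id order K1..K16
    kernels.sort(key=lambda k: int(k.id[1:]))
    return KernelBank(tuple(kernels))


def reference_laplacian_3x3(variant: str) -> np.ndarray:
    """Classic 3x3 discrete Laplacian stencils (positive-center convention).

    ``four_neighbor``: center +4, the 4-connected cross at -1.
    ``eight_neighbor``: center +8, all eight neighbors at -1.
    """
    if variant == "four_neighbor":
        return np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], dtype=np.int64)
    if variant == "eight_neighbor":
        return np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.int64)
    raise ValueError(
        f"unknown Laplacian variant {variant!r}; expected 'four_neighbor' or 'eight_neighbor'"
    )


def kernel_bank_checksum(bank: KernelBank | None = None) -> str:
    """SHA-256 over the canonical JSON dump; embedded in reports for provenance."""
    if bank is None:
        bank = build_kernel_bank()
    payload = json.dumps(bank.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
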