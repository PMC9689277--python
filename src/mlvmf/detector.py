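"""Impulse detection: directional variation responses, minima, threshold rule.

For a round's eight kernels K_i and the three color planes I_j, the variation
response is V_ij(x, y) = |K_i (*) I_j| — the absolute value of the 5x5
correlation, computed in exact integer arithmetic under replicate border
padding.  A pixel therefore carries 8 x 3 = 24 variation measurements per
round.  The per-pixel minimum M(x, y) over those 24 entries, with its
(kernel, channel) argmin, drives the declaration rule:

    flagged(x, y)  <=>  M(x, y) > T  and  I_{argmin channel}(x, y) in {0, 255}

Taking the *minimum* means a pixel is declared impulse-like only when every
direction on every channel shows a strong variation; a genuine edge or line
always has one quiet direction.  The 0/255 check then rejects high-contrast
clean structure, since only the extreme intensities can be salt or pepper.
The intensity test always reads the round's input image (the original image
in round one, the once-cleaned image in round two).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kernels import Kernel, KernelBank, Round

__all__ = [
    "VariationTensor",
    "MinVariationMap",
    "DetectionMask",
    "convolve_abs",
    "variation_tensor",
    "min_variation",
    "detect",
    "DEFAULT_THRESHOLD",
]

#: Detection threshold on the minimum variation, both rounds.
DEFAULT_THRESHOLD = 75.0

_BORDER_MODES = {"replicate": "nearest", "reflect": "reflect", "zero": "constant"}


@dataclass(frozen=True)
class VariationTensor:
    """Responses V_ij >= 0 stacked as (kernel, channel, row, col)."""

    values: np.ndarray  # (8, 3, H, W) int64, nonnegative
    round: Round
    kernel_ids: tuple[str, ...]  # id order of axis 0 (stable argmin order)


@dataclass(frozen=True)
class MinVariationMap:
    """Per-pixel minimum over the 24 (kernel, channel) responses."""

    M: np.ndarray  # (H, W)
    argmin_kernel: np.ndarray  # (H, W) index into kernel_ids
    argmin_channel: np.ndarray  # (H, W) in {0: red, 1: green, 2: blue}
    kernel_ids: tuple[str, ...]
    round: Round


@dataclass(frozen=True)
class DetectionMask:
    """Pixels declared impulsive in one round."""

    flagged: np.ndarray  # (H, W) bool
    round: Round
    threshold_used: float

    @property
    def count(self) -> int:
        return int(self.flagged.sum())


def convolve_abs(channel: np.ndarray, kernel: Kernel | np.ndarray, border: str = "replicate") -> np.ndarray:
    """|K (*) I| for one channel: exact int64 correlation, then absolute value.

    response(x, y) = | sum_{u,v} K(u, v) * I(x+u-2, y+v-2) |, out-of-range
    samples supplied by the border policy (default replicate/edge extension,
    so border pixels get the full 24 measurements without spurious responses).
    """
    weights = kernel.weights if isinstance(kernel, Kernel) else np.asarray(kernel)
    channel = np.asarray(channel)
    if channel.ndim != 2 or channel.size == 0:
        raise ValueError(f"expected a nonempty 2-D channel, got shape {channel.shape}")
    if border not in _BORDER_MODES:
        raise ValueError(f"unknown border policy {border!r}; expected one of {sorted(_BORDER_MODES)}")
    resp = ndimage.correlate(
        channel.astype(np.int64), weights.astype(np.int64), mode=_BORDER_MODES[border], cval=0
    )
    return np.abs(resp)


def variation_tensor(
    image: np.ndarray, bank: KernelBank, round: Round | str, border: str = "replicate"
) -> VariationTensor:
    """Stack convolve_abs over the round's 8 kernels x 3 color planes."""
    round = Round(round)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    kernels = bank.round_kernels(round)
    h, w, _ = image.shape
    values = np.empty((len(kernels), 3, h, w), dtype=np.int64)
    for ki, kernel in enumerate(kernels):
        for ch in range(3):
            values[ki, ch] = convolve_abs(image[:, :, ch], kernel, border)
    return VariationTensor(values=values, round=round, kernel_ids=tuple(k.id for k in kernels))


def min_variation(t: VariationTensor) -> MinVariationMap:
    """Per-pixel minimum of the 24 responses with deterministic argmin.

    Ties resolve to the smallest (kernel, channel) pair in id order: the
    tensor is flattened kernel-major and ``argmin`` returns the first hit.
    """
    nk, nc, h, w = t.values.shape
    flat = t.values.reshape(nk * nc, h, w)
    idx = flat.argmin(axis=0)
    m = np.take_along_axis(flat, idx[None], axis=0)[0]
    return MinVariationMap(
        M=m,
        argmin_kernel=(idx // nc).astype(np.intp),
        argmin_channel=(idx % nc).astype(np.intp),
        kernel_ids=t.kernel_ids,
        round=t.round,
    )


def detect(image: np.ndarray, mv: MinVariationMap, threshold: float = DEFAULT_THRESHOLD) -> DetectionMask:
    """Apply the threshold + extreme-intensity rule to one round's minima.

    ``image`` must be the round's input image (the same one the variation
    tensor was computed from); its value on the argmin channel is what the
    0/255 test reads.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    image = np.asarray(image)
    h, w = mv.M.shape
    if image.shape != (h, w, 3):
        raise ValueError(f"image shape {image.shape} does not match minima {(h, w)}")
    rows, cols = np.indices((h, w))
    at_argmin = image[rows, cols, mv.argmin_channel]
    flagged = (mv.M > threshold) & ((at_argmin == 0) | (at_argmin == 255))
    return DetectionMask(flagged=flagged, round=mv.round, threshold_used=float(threshold))
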