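"""Restoration quality metrics: PSNR (dB) and normalized color difference.

PSNR is computed from the channel-averaged mean squared error,

    MSE_l = (1 / nm) * sum_{i,j} (I_l(i,j) - Ic_l(i,j))^2,   l in {r, g, b}
    MSE   = (MSE_r + MSE_g + MSE_b) / 3
    PSNR  = 10 * log10(255^2 / MSE)        [dB, +inf when MSE = 0]

The NCD measures perceptual color distortion in the analog BT.601 YUV space
(Y = 0.299 R + 0.587 G + 0.114 B, U = 0.492 (B - Y), V = 0.877 (R - Y),
computed in floating point, no quantization):

    NCD = sum_ij ||YUV(i,j) - YUVc(i,j)||_2  /  sum_ij ||YUV(i,j)||_2

with the original image in the denominator, so NCD = 0 iff the images agree
and NCD = 1 exactly against an all-black restoration.  The transform matrix
is a module constant so alternate YUV conventions can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["QualityScores", "psnr", "rgb_to_yuv", "ncd", "quality_scores", "YUV_MATRIX"]

#: Analog BT.601 RGB->YUV matrix (rows: Y, U, V).
YUV_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.492 * -0.299, 0.492 * -0.587, 0.492 * (1 - 0.114)],
        [0.877 * (1 - 0.299), 0.877 * -0.587, 0.877 * -0.114],
    ],
    dtype=np.float64,
)


@dataclass(frozen=True)
class QualityScores:
    psnr_db: float  # math.inf when the images are identical
    ncd: float
    mse_per_channel: tuple[float, float, float]


def _check_pair(original: np.ndarray, filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    original = np.asarray(original)
    filtered = np.asarray(filtered)
    if original.shape != filtered.shape:
        raise ValueError(f"image shapes differ: {original.shape} vs {filtered.shape}")
    if original.ndim != 3 or original.shape[2] != 3:
        raise ValueError(f"expected HxWx3 images, got shape {original.shape}")
    return original, filtered


def psnr(original: np.ndarray, filtered: np.ndarray) -> tuple[float, tuple[float, float, float]]:
    """Peak signal-to-noise ratio in dB and the per-channel MSE triple."""
    original, filtered = _check_pair(original, filtered)
    diff = original.astype(np.float64) - filtered.astype(np.float64)
    mse_per_channel = tuple(float(np.mean(diff[:, :, c] ** 2)) for c in range(3))
    mse = sum(mse_per_channel) / 3.0
    if mse == 0.0:
        return math.inf, mse_per_channel
    return 10.0 * math.log10(255.0**2 / mse), mse_per_channel


def rgb_to_yuv(image: np.ndarray) -> np.ndarray:
    """Per-pixel linear BT.601 transform; float output, gray maps to (Y, 0, 0)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    return image.astype(np.float64) @ YUV_MATRIX.T


def ncd(original: np.ndarray, filtered: np.ndarray) -> float:
    """Normalized color difference; 0 iff identical, lower is better."""
    original, filtered = _check_pair(original, filtered)
    yuv_o = rgb_to_yuv(original)
    yuv_f = rgb_to_yuv(filtered)
    denom = float(np.sqrt((yuv_o**2).sum(axis=2)).sum())
    if denom == 0.0:
        raise ValueError("NCD undefined: the original image is all black (zero YUV norm)")
    num = float(np.sqrt(((yuv_o - yuv_f) ** 2).sum(axis=2)).sum())
    return num / denom


def quality_scores(original: np.ndarray, filtered: np.ndarray) -> QualityScores:
    """PSNR + NCD bundle against a clean reference."""
    psnr_db, mse_per_channel = psnr(original, filtered)
    return QualityScores(psnr_db=psnr_db, ncd=ncd(original, filtered), mse_per_channel=mse_per_channel)
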