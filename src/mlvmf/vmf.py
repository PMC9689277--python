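"""Vector median filtering over 3x3 RGB windows.

The vector median of a window is the member vector minimizing the sum of
norm-distances to all other members; unlike channelwise median filtering it
never invents a color that was not present in the window.  Flagged pixels
are replaced in batch: every replacement is computed from the round's input
image before any is written, so the result is independent of scan order.
"""

from __future__ import annotations

import numpy as np

from .detector import DetectionMask

__all__ = ["vector_median", "vmf_replace", "vmf_full", "NORMS"]

NORMS = ("L1", "L2")


def _distance_sums(vectors: np.ndarray, norm: str) -> np.ndarray:
    """Sum of pairwise distances, shape (..., k) for input (..., k, 3)."""
    if norm == "L1":
        v = vectors.astype(np.int64)
        diff = np.abs(v[..., :, None, :] - v[..., None, :, :]).sum(axis=-1)
    elif norm == "L2":
        v = vectors.astype(np.float64)
        diff = np.sqrt(((v[..., :, None, :] - v[..., None, :, :]) ** 2).sum(axis=-1))
    else:
        raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")
    return diff.sum(axis=-1)


def vector_median(vectors: np.ndarray, norm: str = "L1") -> np.ndarray:
    """The window vector with minimal aggregate distance to the others.

    ``vectors`` is a (k, 3) array, k in 1..9, listed in raster order; ties
    resolve to the earliest vector.  The result is always one of the inputs.
    """
    vectors = np.asarray(vectors)
    if vectors.ndim != 2 or vectors.shape[1] != 3 or vectors.shape[0] == 0:
        raise ValueError(f"expected a nonempty (k, 3) window, got shape {vectors.shape}")
    idx = int(_distance_sums(vectors, norm).argmin())
    return vectors[idx].copy()


def _windows(image: np.ndarray) -> np.ndarray:
    """All 3x3 windows under replicate padding, shape (H, W, 9, 3) raster order."""
    padded = np.pad(image, ((1, 1), (1, 1), (0, 0)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(0, 1))
    # (H, W, ch, wr, wc) -> (H, W, wr, wc, ch) -> (H, W, 9, ch)
    win = win.transpose(0, 1, 3, 4, 2)
    h, w = image.shape[:2]
    return win.reshape(h, w, 9, 3)


def vmf_replace(image: np.ndarray, mask: DetectionMask | np.ndarray, norm: str = "L1") -> np.ndarray:
    """Replace flagged pixels by their 3x3 vector median; others untouched.

    All medians are read from ``image`` itself (batch semantics), so a
    flagged pixel's replacement never depends on another replacement.
    """
    flagged = mask.flagged if isinstance(mask, DetectionMask) else np.asarray(mask, dtype=bool)
    image = np.asarray(image)
    if flagged.shape != image.shape[:2]:
        raise ValueError(f"mask shape {flagged.shape} does not match image {image.shape[:2]}")
    out = image.copy()
    if not flagged.any():
        return out
    rows, cols = np.nonzero(flagged)
    padded = np.pad(image, ((1, 1), (1, 1), (0, 0)), mode="edge")
    # gather the 9 window members for each flagged pixel, raster order
    dr, dc = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    wr = rows[:, None] + dr.ravel()[None, :]  # padded coords
    wc = cols[:, None] + dc.ravel()[None, :]
    vectors = padded[wr, wc]  # (n, 9, 3)
    best = _distance_sums(vectors, norm).argmin(axis=-1)
    out[rows, cols] = vectors[np.arange(len(rows)), best]
    return out


def vmf_full(image: np.ndarray, norm: str = "L1") -> np.ndarray:
    """Whole-image 3x3 vector median filter (the classic VMF baseline)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    win = _windows(image)
    best = _distance_sums(win, norm).argmin(axis=-1)  # (H, W)
    h, w = image.shape[:2]
    rows, cols = np.indices((h, w))
    return win[rows, cols, best].astype(image.dtype)
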