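"""Lossless 8-bit image I/O.

Images are held internally as HxWx3 uint8 arrays in fixed RGB channel order
(0-based row, column indexing, row-major).  Grayscale sources are replicated
to three channels on load; an image whose channels are all equal collapses
back to one channel when saved to a grayscale container (PGM).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image", "SUPPORTED_SUFFIXES"]

SUPPORTED_SUFFIXES = {".png", ".ppm", ".pgm", ".pnm", ".tif", ".tiff", ".bmp"}
_LOSSY_SUFFIXES = {".jpg", ".jpeg", ".webp"}
_GRAY_SUFFIXES = {".pgm"}


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit raster image as HxWx3 uint8 RGB."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix not in SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported image format {suffix!r} for {path}; supported: {sorted(SUPPORTED_SUFFIXES)}"
        )
    try:
        data = np.asarray(iio.imread(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"could not read image {path} (detected format {suffix}): {exc}") from exc
    if data.dtype != np.uint8:
        raise ValueError(
            f"{path} has {data.dtype} samples; only 8-bit images are supported — "
            "requantize to uint8 before filtering"
        )
    if data.ndim == 2:  # grayscale -> replicate
        data = np.repeat(data[:, :, None], 3, axis=2)
    elif data.ndim == 3 and data.shape[2] == 4:  # drop alpha
        data = data[:, :, :3]
    if data.ndim != 3 or data.shape[2] != 3:
        raise ValueError(f"{path}: unsupported sample layout {data.shape}")
    return np.ascontiguousarray(data)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write losslessly; grayscale-collapsible images stored 1-channel in PGM."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _LOSSY_SUFFIXES:
        raise ValueError(f"refusing lossy format {suffix!r}; use PNG/PPM/PGM/TIFF/BMP")
    if suffix not in SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image format {suffix!r}; supported: {sorted(SUPPORTED_SUFFIXES)}")
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 uint8 image, got {image.dtype} {image.shape}")
    if suffix in _GRAY_SUFFIXES:
        if not (np.array_equal(image[:, :, 0], image[:, :, 1]) and np.array_equal(image[:, :, 0], image[:, :, 2])):
            raise ValueError(f"cannot save a color image to grayscale container {suffix!r}")
        iio.imwrite(path, image[:, :, 0])
    else:
        iio.imwrite(path, image)
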