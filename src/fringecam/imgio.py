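"""Image and mask I/O (PNG/TIFF/JPEG in, PNG/TIFF out)."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
import tifffile


def read_image(path) -> np.ndarray:
    """Read a raster and normalize to float in [0, 1] (grayscale or RGB)."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return arr


def read_mask(path) -> np.ndarray:
    """Read a 0/255 PNG mask as boolean."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (np.iinfo(arr.dtype).max // 2 if np.issubdtype(arr.dtype, np.integer) else 0.5)


def write_png(path, img: np.ndarray, bitdepth: int = 8) -> None:
    """Write a float [0, 1] raster as 8- or 16-bit grayscale/RGB PNG."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 8:
        iio.imwrite(path, np.round(arr * 255).astype(np.uint8))
    elif bitdepth == 16:
        iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    else:
        raise ValueError("bitdepth must be 8 or 16")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def write_float_tiff(path, img: np.ndarray) -> None:
    """Write a floating-point intermediate (observer-space) image."""
    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
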