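"""Image file I/O with explicit physical calibration.

There is deliberately no default pixel size: every downstream quantity is
physical, so calibration must always be supplied by the caller or config.
Intensities are rescaled to [0, 1] by the container's bit depth on read
and quantized back only on write.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import CalibratedImage

__all__ = ["MultiChannelError", "load_image", "save_image"]


class MultiChannelError(ValueError):
    """Multi-channel image given without an explicit conversion flag."""


def load_image(path, pixel_size: float, to_gray: bool = False) -> CalibratedImage:
    """Read a TIFF/PNG as a calibrated [0, 1] grayscale field.

    Multi-channel inputs raise :class:`MultiChannelError` unless
    ``to_gray`` is set, in which case channels are averaged (luminance
    mean).
    """
    if pixel_size is None or not pixel_size > 0:
        raise ValueError("an explicit pixel_size (nm/pixel) is required")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        if not to_gray:
            raise MultiChannelError(
                f"{path.name} has {arr.shape[-1]} channels; pass to_gray=True"
            )
        arr = arr.astype(np.float64).mean(axis=-1)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = arr.astype(np.float64)
    return CalibratedImage(np.clip(arr, 0.0, 1.0), pixel_size,
                           source_id=str(path))


def save_image(image: CalibratedImage, path, bit_depth: int = 16) -> None:
    """Write as 16-bit TIFF or 8-bit PNG (quantization happens here only)."""
    path = Path(path)
    if bit_depth == 16:
        data = np.round(image.pixels * 65535).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(image.pixels * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
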