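"""Calibrated image container.

Every physical quantity in this package (diameters, areas, wall
thicknesses, lamellar periods) is derived from pixel measurements through
an explicit nm/pixel calibration, so the raw array and its pixel size
travel together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalibratedImage"]


@dataclass
class CalibratedImage:
    """A 2-D grayscale field with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite intensities in [0, 1].
    pixel_size
        Physical edge length of one pixel, in nanometres. Must be > 0;
        there is no default — calibration is always explicit.
    source_id
        Free-text provenance (file path, simulator scene id, ...).
    """

    pixels: np.ndarray
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0 (nm/pixel)")
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """New image with the same calibration and provenance."""
        return CalibratedImage(pixels, self.pixel_size, self.source_id)

    def nm_to_px(self, length_nm: float) -> float:
        return float(length_nm) / self.pixel_size

    def px_to_nm(self, length_px: float) -> float:
        return float(length_px) * self.pixel_size
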