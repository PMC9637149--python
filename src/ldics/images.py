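"""In-memory containers for calibrated 2D microscopy images and hypha masks.

An :class:`Image2D` is a plain non-negative intensity grid plus the physical
pixel size in µm/pixel — everything downstream (droplet densities in µm⁻²,
diameters in µm) hangs off that calibration.  A :class:`HyphaMask` marks the
in-hypha pixels of a matching image and carries the hypha area used to
normalize droplet counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class Image2D:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size_um
        Physical size of one pixel in µm (square pixels assumed).
    channel
        Free-form channel label, e.g. ``"THG"`` or ``"TPEF"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "THG"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Return a copy of this image with replaced pixel data."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float, channel: str = "THG") -> "Image2D":
        data = tifffile.imread(path)
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        return cls(pixels=np.asarray(data, dtype=np.float64),
                   pixel_size_um=pixel_size_um, channel=channel)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.pixels.astype(np.float32))


@dataclass
class HyphaMask:
    """Boolean in-hypha mask with the pixel calibration of its source image."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_um2(self) -> float:
        """Hypha area in µm² (true-pixel count × pixel area)."""
        return float(self.mask.sum()) * self.pixel_size_um ** 2

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())

    @property
    def n_outside(self) -> int:
        return int(self.mask.size - self.mask.sum())

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, (self.mask.astype(np.uint8) * 255))
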