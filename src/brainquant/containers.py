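"""In-memory containers shared by every pipeline stage.

Coordinate convention (used package-wide): pixel rasters are indexed
``[row, col]`` with the origin at the image top-left, y increasing downward.
Pixel ``(i, j)`` occupies the half-open square ``[j, j+1) x [i, i+1)`` in
pixel space; its center is at ``(j + 0.5, i + 0.5)``.  Physical coordinates
are obtained only by multiplying pixel coordinates by ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SectionImage", "BinaryMask"]


@dataclass
class SectionImage:
    """A multi-channel 2-D fluorescence section image.

    Parameters
    ----------
    pixels
        Integer raster of shape ``(n_channels, height, width)``.
    channel_names
        Ordered channel names; the pipeline expects DAPI, DsRed and GFP.
    pixel_size_um
        Physical size of one pixel in micrometres (isotropic).
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    source_path: Path | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must have shape (channels, height, width)")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each channel."""
        return self.pixels.shape[1:]

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D raster of a named channel (a view, not a copy)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[idx]

    def average_channel(self) -> np.ndarray:
        """Mean of all channels as float64 (used by the tissue classifier)."""
        return self.pixels.mean(axis=0, dtype=np.float64)

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "SectionImage":
        """Axis-aligned crop in pixel coordinates (half-open bounds)."""
        return SectionImage(
            self.pixels[:, row0:row1, col0:col1].copy(),
            self.channel_names,
            self.pixel_size_um,
            self.source_path,
        )


@dataclass
class BinaryMask:
    """Boolean occupancy raster tied to a SectionImage geometry."""

    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def area_um2(self) -> float:
        return float(self.data.sum()) * self.pixel_size_um**2

    def area_mm2(self) -> float:
        return self.area_um2() / 1e6

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_size_um: float) -> "BinaryMask":
        return cls(np.ones(shape, dtype=bool), pixel_size_um)

    @classmethod
    def empty(cls, shape: tuple[int, int], pixel_size_um: float) -> "BinaryMask":
        return cls(np.zeros(shape, dtype=bool), pixel_size_um)
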