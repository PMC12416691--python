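"""Image containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MONOCHROME1 = "monochrome1"
MONOCHROME2 = "monochrome2"
UNKNOWN = "unknown"

#: side of a standardized phantom image, pixels
STD_SIZE = 224
#: side of one grid-cell subimage, pixels
TILE_SIZE = STD_SIZE // 4


@dataclass
class RawImage:
    """A 2D grayscale radiograph as read from disk or rendered.

    ``pixels`` are finite non-negative intensities; ``photometric``
    states whether high values are dark (monochrome1) or bright
    (monochrome2); ``bit_depth`` gives the nominal dynamic range
    (``2**bit_depth - 1``) for integer data.  Float images are assumed
    to live on [0, 1] regardless of ``bit_depth``.
    """

    pixels: np.ndarray
    photometric: str = MONOCHROME2
    bit_depth: int = 16

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.photometric not in (MONOCHROME1, MONOCHROME2, UNKNOWN):
            raise ValueError(f"unknown photometric {self.photometric!r}")

    @property
    def max_value(self) -> float:
        """Top of the dynamic range used for polarity inversion."""
        if np.issubdtype(self.pixels.dtype, np.floating):
            return 1.0
        return float(2 ** self.bit_depth - 1)


@dataclass
class StandardizedImage:
    """A 224x224, [0, 1]-normalized, grid-aligned phantom image."""

    pixels: np.ndarray
    #: applied rotation (degrees, counterclockwise, total), crop box in the
    #: source frame (y0, x0, y1, x1) and normalization window (min, max)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (STD_SIZE, STD_SIZE):
            raise ValueError(
                f"standardized image must be {STD_SIZE}x{STD_SIZE}, "
                f"got {self.pixels.shape}"
            )
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("standardized pixels must lie in [0, 1]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)


@dataclass
class Subimage:
    """One 56x56 grid-cell tile of a standardized phantom image."""

    pixels: np.ndarray
    lesion_type: str
    rank: int
    grid_cell: int  # 1-based, row-major

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (TILE_SIZE, TILE_SIZE):
            raise ValueError(
                f"subimage must be {TILE_SIZE}x{TILE_SIZE}, got {self.pixels.shape}"
            )
        if not 1 <= self.grid_cell <= 16:
            raise ValueError("grid_cell must be 1..16")
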