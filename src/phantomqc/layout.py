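"""The 4x4 lesion grid layout shared by the generator and the scorers.

The accreditation phantom embeds 16 artificial lesions in a wax insert:
six fibers, five speck groups (six specks each) and five masses, with
size and contrast decreasing with rank (rank 1 = largest).  The grid
cell occupied by each lesion is fixed for a given phantom model; the
default map below places fibers in cells 1-6, speck groups in 7-11 and
masses in 12-16 (row-major, 1-based), ranks in descending size.

All geometry is expressed in *cell fractions* — unit coordinates within
a grid cell — so the same layout serves the renderer (cells of whatever
pixel size the canvas gives) and the rule scorers (56x56 tiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

FIBER = "fiber"
SPECKS = "specks"
MASS = "mass"

LESION_TYPES = (FIBER, SPECKS, MASS)

#: number of lesions per feature type
TYPE_COUNTS = {FIBER: 6, SPECKS: 5, MASS: 5}

#: feature-total thresholds for qualification ("at least")
QUALIFY_THRESHOLDS = {FIBER: 4.0, SPECKS: 3.0, MASS: 3.0}


def _speck_pattern() -> tuple[tuple[float, float], ...]:
    """Six speck offsets (cell fractions, relative to cell center):
    a pentagon plus its center, the conventional cluster arrangement."""
    pts = [(0.0, 0.0)]
    r = 0.26
    for k in range(5):
        a = -math.pi / 2 + 2 * math.pi * k / 5
        pts.append((r * math.sin(a), r * math.cos(a)))  # (dy, dx)
    return tuple(pts)


@dataclass(frozen=True)
class GridLayout:
    """Cell map plus canonical per-rank lesion geometry.

    Sizes are fractions of the cell side; contrasts are intensity deltas
    above the insert background on the normalized [0, 1] scale.
    """

    # cell index (0-based, row-major) -> (lesion_type, rank 1-based)
    cell_map: tuple[tuple[str, int], ...] = field(
        default_factory=lambda: tuple(
            [(FIBER, r) for r in range(1, 7)]
            + [(SPECKS, r) for r in range(1, 6)]
            + [(MASS, r) for r in range(1, 6)]
        )
    )

    fiber_length: tuple[float, ...] = (0.85, 0.78, 0.70, 0.62, 0.54, 0.46)
    fiber_width: float = 0.055
    fiber_contrast: tuple[float, ...] = (0.30, 0.27, 0.24, 0.21, 0.18, 0.16)
    #: fiber axis angle in degrees (45 = top-left to bottom-right diagonal)
    fiber_angle_deg: float = 45.0

    speck_diameter: tuple[float, ...] = (0.16, 0.14, 0.12, 0.105, 0.09)
    speck_contrast: tuple[float, ...] = (0.34, 0.30, 0.27, 0.24, 0.21)
    speck_offsets: tuple[tuple[float, float], ...] = field(
        default_factory=_speck_pattern
    )

    mass_diameter: tuple[float, ...] = (0.66, 0.58, 0.50, 0.44, 0.38)
    mass_contrast: tuple[float, ...] = (0.26, 0.23, 0.20, 0.17, 0.14)

    def __post_init__(self):
        counts = {t: 0 for t in LESION_TYPES}
        for t, _ in self.cell_map:
            counts[t] += 1
        if counts != TYPE_COUNTS:
            raise ValueError(f"cell map must contain {TYPE_COUNTS}, got {counts}")
        if len(self.cell_map) != 16:
            raise ValueError("cell map must have 16 entries")

    def cell_of(self, lesion_type: str, rank: int) -> int:
        """0-based cell index of a lesion."""
        return self.cell_map.index((lesion_type, rank))

    def lesion_at(self, cell: int) -> tuple[str, int]:
        """(lesion_type, rank) occupying a 0-based cell index."""
        return self.cell_map[cell]

    def size_frac(self, lesion_type: str, rank: int) -> float:
        """Characteristic size (cell fraction): fiber length, speck
        diameter, or mass diameter."""
        i = rank - 1
        if lesion_type == FIBER:
            return self.fiber_length[i]
        if lesion_type == SPECKS:
            return self.speck_diameter[i]
        if lesion_type == MASS:
            return self.mass_diameter[i]
        raise ValueError(f"unknown lesion type {lesion_type!r}")

    def contrast(self, lesion_type: str, rank: int) -> float:
        i = rank - 1
        if lesion_type == FIBER:
            return self.fiber_contrast[i]
        if lesion_type == SPECKS:
            return self.speck_contrast[i]
        if lesion_type == MASS:
            return self.mass_contrast[i]
        raise ValueError(f"unknown lesion type {lesion_type!r}")


DEFAULT_LAYOUT = GridLayout()
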