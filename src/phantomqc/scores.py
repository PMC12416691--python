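"""Lesion score labels and the guideline scoring policy.

Each of the 16 lesions in an ACR-style accreditation phantom is graded
0.0 (not visible), 0.5 (partially visible at the correct location) or
1.0 (fully visible).  An auxiliary ``N/A`` grade marks lesions that are
faintly visible but fall short of the 0.5 visibility criterion; N/A
never contributes points to a feature total and is excluded from
classifier training.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Score(enum.Enum):
    """Categorical lesion grade."""

    ZERO = "0.0"
    HALF = "0.5"
    FULL = "1.0"
    NA = "NA"

    @property
    def points(self) -> float:
        """Numeric contribution to a feature total (N/A contributes 0)."""
        return {"0.0": 0.0, "0.5": 0.5, "1.0": 1.0, "NA": 0.0}[self.value]

    @property
    def is_na(self) -> bool:
        return self is Score.NA

    def __str__(self) -> str:  # CSV-friendly
        return self.value

    @classmethod
    def from_value(cls, v) -> "Score":
        """Coerce a float/str label (0.0, 0.5, 1.0, 'NA') to a Score."""
        if isinstance(v, Score):
            return v
        if isinstance(v, str):
            s = v.strip().upper()
            if s in ("NA", "N/A"):
                return cls.NA
            v = float(s)
        if v == 0.0:
            return cls.ZERO
        if v == 0.5:
            return cls.HALF
        if v == 1.0:
            return cls.FULL
        raise ValueError(f"not a valid lesion score: {v!r}")


#: ordering used by monotonicity checks: 0.0 < NA < 0.5 < 1.0
SCORE_ORDER = {Score.ZERO: 0, Score.NA: 1, Score.HALF: 2, Score.FULL: 3}


@dataclass(frozen=True)
class ScorePolicy:
    """Tunable readings of the guideline wording.

    The guideline text leaves three points open; each is a configurable
    default here so that ground-truth labels are well defined.

    Parameters
    ----------
    four_specks_full:
        The 1.0 rule reads "more than 4 of 6 specks" and the 0.5 rule
        covers "2-3 visible specks"; a count of exactly 4 is not covered
        by either.  Default assigns 1.0 (consistent with learned-model
        score transitions observed at 3-4 visible specks).
    speck_floor:
        A speck counts as "distinctly visible" when its opacity is at
        least this fraction of the nominal contrast.
    fiber_na_band:
        ``(lo, hi]`` band of longest-continuous-fraction values mapped
        to N/A: visible but below the 0.5 criterion.  Below ``lo`` the
        fiber grades 0.0.
    fiber_subhalf_na:
        When True, a detected fiber whose longest run is <= 1/2 grades
        N/A (within the band); when False it grades 0.0.
    mass_na_contrast_band:
        Masses with contrast in ``(lo, hi)`` — as a fraction of the
        detectability floor — are ambiguous: N/A instead of 0.0.
    mass_contrast_floor:
        Minimum absolute contrast for a mass to count as present.
    """

    four_specks_full: bool = True
    speck_floor: float = 0.3
    fiber_na_band: tuple[float, float] = (0.1, 0.5)
    fiber_subhalf_na: bool = True
    mass_na_contrast_band: tuple[float, float] = (0.5, 1.0)
    mass_contrast_floor: float = 0.02
    fiber_contrast_floor: float = 0.02

    def score_fiber_fraction(self, longest_run: float, full: bool,
                             contrast: float) -> Score:
        """Grade a fiber from its longest continuous visible fraction."""
        if contrast < self.fiber_contrast_floor or longest_run <= 0.0:
            return Score.ZERO
        if full:
            return Score.FULL
        if longest_run > 0.5:
            return Score.HALF
        lo, hi = self.fiber_na_band
        if self.fiber_subhalf_na and lo < longest_run <= hi:
            return Score.NA
        return Score.ZERO

    def score_speck_count(self, count: int) -> Score:
        if count >= 5:
            return Score.FULL
        if count == 4:
            return Score.FULL if self.four_specks_full else Score.HALF
        if count in (2, 3):
            return Score.HALF
        return Score.ZERO

    def score_mass(self, contrast: float, circular_fraction: float) -> Score:
        floor = self.mass_contrast_floor
        if contrast < floor * self.mass_na_contrast_band[0]:
            return Score.ZERO
        if contrast < floor * self.mass_na_contrast_band[1]:
            return Score.NA
        if circular_fraction > 0.75:
            return Score.FULL
        return Score.HALF


DEFAULT_POLICY = ScorePolicy()
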