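"""Deterministic guideline scorers for standardized lesion tiles.

These mirror the criteria radiologists apply: fibers are graded by the
longest continuous visible segment along the expected axis, speck
groups by the count of distinctly visible specks at the six expected
positions, masses by presence and by the fraction of the contour
consistent with the best-fit circle.  Expected positions, axes and
nominal contrasts come from the grid layout map — nothing is learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from .images import TILE_SIZE, Subimage
from .layout import DEFAULT_LAYOUT, FIBER, MASS, SPECKS, GridLayout
from .scores import DEFAULT_POLICY, Score, ScorePolicy


@dataclass
class FiberDiagnostics:
    detected_mask: np.ndarray
    longest_run_fraction: float
    visible_fraction: float
    orientation_ok: bool = True


@dataclass
class SpeckDiagnostics:
    visible_count: int
    per_speck_contrast: np.ndarray


@dataclass
class MassDiagnostics:
    present: bool
    circular_contour_fraction: float | None


def _background(tile: np.ndarray, border: int = 4) -> tuple[float, float]:
    """(median, robust noise std) of the tile's margin frame."""
    frame = np.concatenate(
        [
            tile[:border].ravel(),
            tile[-border:].ravel(),
            tile[border:-border, :border].ravel(),
            tile[border:-border, -border:].ravel(),
        ]
    )
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, 1.4826 * mad


def _bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# fiber


def score_fiber(
    sub: Subimage,
    layout: GridLayout = DEFAULT_LAYOUT,
    policy: ScorePolicy = DEFAULT_POLICY,
    noise_sigmas: float = 5.0,
    min_peak: float = 0.12,
    full_fraction: float = 0.95,
) -> tuple[Score, FiberDiagnostics]:
    """Grade a fiber tile by its longest continuous visible segment.

    The tile is lightly smoothed and sampled along the expected fiber
    axis (a matched line probe that takes the maximum over small
    perpendicular offsets).  Samples above half the peak contrast count
    as visible — a scale-free threshold, since the standardization
    window varies with the brightest lesion of each phantom, and the
    half-peak crossing of a blurred edge sits at the true segment end.
    The longest run as a fraction of the expected length maps to the
    grade: ~full -> 1.0, > 1/2 -> 0.5, detected but sub-half -> N/A
    (or 0.0 per policy), nothing -> 0.0.
    """
    if sub.lesion_type != FIBER:
        raise ValueError(f"expected a fiber tile, got {sub.lesion_type!r}")
    tile = ndimage.gaussian_filter(sub.pixels, 0.7)
    bg, noise = _background(tile)

    c = TILE_SIZE
    cy = cx = (c - 1) / 2.0
    th = np.deg2rad(layout.fiber_angle_deg)
    dy, dx = np.sin(th), np.cos(th)
    length = layout.fiber_length[sub.rank - 1] * c
    n = max(24, int(round(length * 2)))
    t = (np.arange(n) / (n - 1) - 0.5) * length
    vals = np.full(n, -np.inf)
    for off in (-1.5, 0.0, 1.5):
        ys = cy + t * dy + off * dx
        xs = cx + t * dx - off * dy
        vals = np.maximum(vals, _bilinear(tile, ys, xs))
    peak = float(vals.max() - bg)
    if peak < max(noise_sigmas * noise, min_peak):
        diag = FiberDiagnostics(
            detected_mask=np.zeros(n, bool), longest_run_fraction=0.0,
            visible_fraction=0.0,
        )
        return Score.ZERO, diag
    visible = (vals - bg) > 0.5 * peak

    # longest run of visible samples, as a fraction of expected length
    best = run = 0
    for v in visible:
        run = run + 1 if v else 0
        best = max(best, run)
    longest = best / n
    frac_visible = float(np.mean(visible))

    full = longest >= full_fraction
    score = policy.score_fiber_fraction(longest, full, 1.0 if visible.any() else 0.0)
    diag = FiberDiagnostics(
        detected_mask=visible,
        longest_run_fraction=float(longest),
        visible_fraction=frac_visible,
    )
    return score, diag


# ---------------------------------------------------------------------------
# specks


def score_specks(
    sub: Subimage,
    layout: GridLayout = DEFAULT_LAYOUT,
    policy: ScorePolicy = DEFAULT_POLICY,
    noise_sigmas: float = 4.0,
    rel_floor: float = 0.3,
    min_floor: float = 0.06,
) -> tuple[Score, SpeckDiagnostics]:
    """Count distinctly visible specks at the six expected positions.

    Each position contributes the peak smoothed contrast within a small
    search window; a speck is "distinctly visible" when it clears the
    noise floor, an absolute floor, and ``rel_floor`` of the brightest
    speck in the tile (scale-free, like the fiber threshold).
    """
    if sub.lesion_type != SPECKS:
        raise ValueError(f"expected a specks tile, got {sub.lesion_type!r}")
    tile = ndimage.gaussian_filter(sub.pixels, 0.6)
    bg, noise = _background(tile)

    c = TILE_SIZE
    cy = cx = (c - 1) / 2.0
    r_search = max(2, int(round(0.05 * c)))
    contrasts = np.zeros(6)
    for i, (oy, ox) in enumerate(layout.speck_offsets):
        py, px = cy + oy * c, cx + ox * c
        y0, y1 = int(py) - r_search, int(py) + r_search + 1
        x0, x1 = int(px) - r_search, int(px) + r_search + 1
        window = tile[max(0, y0) : y1, max(0, x0) : x1]
        contrasts[i] = window.max() - bg
    floor = max(noise_sigmas * noise, rel_floor * contrasts.max(), min_floor)
    count = int(np.sum(contrasts > floor))
    return policy.score_speck_count(count), SpeckDiagnostics(
        visible_count=count, per_speck_contrast=contrasts
    )


# ---------------------------------------------------------------------------
# mass


def score_mass(
    sub: Subimage,
    layout: GridLayout = DEFAULT_LAYOUT,
    policy: ScorePolicy = DEFAULT_POLICY,
    noise_sigmas: float = 4.0,
    min_peak: float = 0.10,
    n_bins: int = 72,
    radial_tol: float = 0.04,
    min_tol_px: float = 0.35,
    min_area_frac: float = 0.1,
) -> tuple[Score, MassDiagnostics]:
    """Grade a mass by presence and contour circularity.

    The lesion is segmented at half its peak contrast (the half-peak
    contour of a blurred shape tracks the true boundary); the subpixel
    contour (marching squares) is binned into ``n_bins`` angular
    sectors around the fitted circle (center = region centroid, radius
    = median boundary distance).  A sector counts as circular when
    every contour point in it lies within the radial tolerance; the
    circular fraction > 3/4 grades 1.0, else 0.5; an absent lesion
    grades 0.0.
    """
    if sub.lesion_type != MASS:
        raise ValueError(f"expected a mass tile, got {sub.lesion_type!r}")
    tile = ndimage.gaussian_filter(sub.pixels, 0.7)
    bg, noise = _background(tile)

    c = TILE_SIZE
    cy = cx = (c - 1) / 2.0
    expected_d = layout.mass_diameter[sub.rank - 1] * c
    r_probe = expected_d / 2.0 + 2.0
    yy, xx = np.mgrid[0:c, 0:c]
    central = np.hypot(yy - cy, xx - cx) <= r_probe
    peak = float(tile[central].max() - bg)
    if peak < max(noise_sigmas * noise, min_peak):
        return Score.ZERO, MassDiagnostics(False, None)
    level = bg + 0.5 * peak
    mask = tile > level
    labels, nlab = ndimage.label(mask)
    if nlab == 0:
        return Score.ZERO, MassDiagnostics(False, None)
    # component containing (or nearest) the expected center
    lab_at = labels[int(round(cy)), int(round(cx))]
    if lab_at == 0:
        sizes = ndimage.sum(mask, labels, index=np.arange(1, nlab + 1))
        coms = ndimage.center_of_mass(mask, labels, np.arange(1, nlab + 1))
        dists = [np.hypot(y - cy, x - cx) for y, x in coms]
        lab_at = 1 + int(np.argmin(dists))
        if dists[lab_at - 1] > 0.25 * c or sizes[lab_at - 1] < 4:
            return Score.ZERO, MassDiagnostics(False, None)
    region = labels == lab_at
    if region.sum() < min_area_frac * np.pi * (expected_d / 4) ** 2:
        return Score.ZERO, MassDiagnostics(False, None)

    contours = measure.find_contours(
        np.where(region, tile, bg).astype(float), level
    )
    if not contours:
        return Score.ZERO, MassDiagnostics(False, None)
    contour = max(contours, key=len)
    my, mx_ = ndimage.center_of_mass(region)
    ry = contour[:, 0] - my
    rx = contour[:, 1] - mx_
    r = np.hypot(ry, rx)
    radius = float(np.median(r))
    if radius < 1.0:
        return Score.ZERO, MassDiagnostics(False, None)
    ang = np.arctan2(ry, rx)
    bins = ((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    tol = max(radial_tol * radius, min_tol_px)
    dev = np.abs(r - radius)
    circ_bins = 0
    occupied = 0
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        occupied += 1
        if dev[sel].max() <= tol:
            circ_bins += 1
    if occupied == 0:
        return Score.ZERO, MassDiagnostics(False, None)
    fraction = circ_bins / occupied
    return policy.score_mass(1.0, fraction), MassDiagnostics(True, float(fraction))


# ---------------------------------------------------------------------------
# dispatch


_SCORERS = {FIBER: score_fiber, SPECKS: score_specks, MASS: score_mass}


def score_tile(
    sub: Subimage,
    layout: GridLayout = DEFAULT_LAYOUT,
    policy: ScorePolicy = DEFAULT_POLICY,
) -> tuple[Score, object]:
    return _SCORERS[sub.lesion_type](sub, layout=layout, policy=policy)


def score_phantom(
    subs: list[Subimage],
    layout: GridLayout = DEFAULT_LAYOUT,
    policy: ScorePolicy = DEFAULT_POLICY,
) -> list[Score]:
    """Type-appropriate grade for each of the 16 tiles (row-major)."""
    if len(subs) != 16:
        raise ValueError("need the complete 16-tile grid")
    return [score_tile(s, layout, policy)[0] for s in subs]


class RuleBasedScorer(BaseEstimator):
    """sklearn-style wrapper: ``predict`` maps tiles to guideline
    grades; ``predict_one`` returns the grade plus diagnostics."""

    def __init__(
        self,
        layout: GridLayout = DEFAULT_LAYOUT,
        policy: ScorePolicy = DEFAULT_POLICY,
    ):
        self.layout = layout
        self.policy = policy

    def fit(self, X=None, y=None):
        return self

    def predict_one(self, sub: Subimage) -> tuple[Score, object]:
        return score_tile(sub, self.layout, self.policy)

    def predict(self, X) -> list[Score]:
        return [self.predict_one(s)[0] for s in X]

    def __call__(self, sub: Subimage) -> Score:
        return self.predict_one(sub)[0]
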