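"""Four-stage standardization of raw phantom radiographs.

1. Format/polarity normalization: invert monochrome1 to monochrome2 so
   the phantom is bright on a dark background.
2. Phantom localization and alignment: Otsu threshold, largest
   connected component, coarse rotation (multiple of 90 degrees chosen
   from the side nearest the component's center of mass) plus a fine
   tilt found by profile-sharpness search, then an initial crop to the
   phantom bounding box that discards borders, embedded text and
   margins.
3. Lesion-area cropping: row/column line-profile analysis locates the
   wax-insert border; a small residual rotation is corrected so the
   lesion grid is right-angle aligned.
4. Intensity normalization and grid division: the min/max window is
   taken over the central rhombus (vertices at the edge midpoints, so
   bright outliers like the acrylic disc marker are ignored), mapped to
   [0, 1], resized to 224x224 and split into 16 56x56 subimages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform
from sklearn.base import BaseEstimator, TransformerMixin

from .images import (
    MONOCHROME1,
    MONOCHROME2,
    STD_SIZE,
    TILE_SIZE,
    UNKNOWN,
    RawImage,
    StandardizedImage,
    Subimage,
)
from .layout import DEFAULT_LAYOUT, GridLayout


class StageError(RuntimeError):
    """A pipeline stage could not process the image."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage
        self.message = message


@dataclass
class PipelineFailure:
    """Structured report for an image the pipeline rejected."""

    stage: str
    message: str


@dataclass
class Localization:
    mask: np.ndarray
    rot90: int
    fine_deg: float
    threshold: float


# ---------------------------------------------------------------------------
# stage 1: polarity


def to_monochrome2(img: RawImage) -> RawImage:
    """Return the image in monochrome2 polarity (phantom bright).

    Monochrome1 data is complemented against its dynamic range; an
    unknown photometric tag is resolved by a border heuristic (the
    border is air: darker than the field in monochrome2).
    """
    photometric = img.photometric
    if photometric == UNKNOWN:
        pix = img.pixels
        b = max(2, min(pix.shape) // 20)
        border = np.concatenate(
            [pix[:b].ravel(), pix[-b:].ravel(), pix[:, :b].ravel(), pix[:, -b:].ravel()]
        )
        photometric = (
            MONOCHROME1 if np.median(border) > np.median(pix) else MONOCHROME2
        )
    if photometric == MONOCHROME2:
        return RawImage(img.pixels, MONOCHROME2, img.bit_depth)
    return RawImage(img.max_value - img.pixels, MONOCHROME2, img.bit_depth)


# ---------------------------------------------------------------------------
# stage 2: localization and alignment

#: np.rot90 turns (CCW) that bring each side to the bottom
_SIDE_TO_ROT90 = {"bottom": 0, "left": 1, "top": 2, "right": 3}


def _rescale01(pix: np.ndarray) -> np.ndarray:
    lo, hi = float(pix.min()), float(pix.max())
    if hi - lo < 1e-12:
        raise StageError("locate_phantom", "flat image")
    return (pix - lo) / (hi - lo)


def estimate_fine_rotation(
    image: np.ndarray,
    max_deg: float = 5.0,
    fine_step: float = 0.1,
    downsample: int = 4,
) -> float:
    """Small rotation (degrees, as passed to ``ndimage.rotate``) that
    maximizes row/column profile-edge sharpness, i.e. axis-aligns the
    dominant rectangular structure.  Two-stage search: 1-degree sweep
    on a downsampled image, then ``fine_step`` refinement.  Ties favor
    the smaller |angle| so an already-aligned image is left alone."""

    def sharpness(img, angle):
        if angle:
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        s = np.sum(np.diff(img.mean(axis=0)) ** 2)
        s += np.sum(np.diff(img.mean(axis=1)) ** 2)
        # small-|angle| preference; the additive term settles flat ties
        return s * (1.0 - 2e-3 * abs(angle)) - 1e-12 * abs(angle)

    small = image[::downsample, ::downsample].astype(float)
    coarse = np.arange(-max_deg, max_deg + 0.5, 1.0)
    best = max(coarse, key=lambda a: sharpness(small, a))
    small2 = image[:: max(1, downsample // 2), :: max(1, downsample // 2)].astype(float)
    lo, hi = best - 1.0, best + 1.0
    angles = np.arange(lo, hi + fine_step / 2, fine_step)
    best = max(angles, key=lambda a: sharpness(small2, a))
    return float(np.round(best, 3))


def locate_phantom(
    img: RawImage,
    min_area_frac: float = 0.005,
    full_frame_frac: float = 0.10,
    fine_max_deg: float = 5.0,
) -> Localization:
    """Find the phantom region and the rotation that moves it to
    bottom-center.

    Otsu's threshold is computed on a 256-bin histogram of the
    min/max-rescaled image (making the stage invariant to affine
    intensity transforms); the largest connected component wins, ties
    broken by lowest centroid.  If the largest component covers less
    than ``full_frame_frac`` of the frame it cannot be a phantom body
    — the frame is then assumed to be phantom-only already (e.g. a
    re-fed standardized image, where Otsu picks out single lesions)
    and passed through unrotated.  Below ``min_area_frac`` the image
    is rejected outright.
    """
    pix = _rescale01(np.asarray(img.pixels, dtype=float))
    t = filters.threshold_otsu(pix, nbins=256)
    binary = pix > t
    labels, n = measure.label(binary, return_num=True)
    if n == 0:
        raise StageError("locate_phantom", "no region above threshold")
    props = measure.regionprops(labels)
    props.sort(key=lambda r: (-r.area, -r.centroid[0]))
    region = props[0]
    if region.area < min_area_frac * pix.size:
        raise StageError("locate_phantom", "largest component below minimum area")
    if region.area < full_frame_frac * pix.size:
        return Localization(
            mask=np.ones_like(binary, dtype=bool), rot90=0, fine_deg=0.0,
            threshold=float(t),
        )
    mask = labels == region.label
    cy, cx = region.centroid
    h, w = pix.shape
    dists = {
        "top": cy,
        "bottom": h - 1 - cy,
        "left": cx,
        "right": w - 1 - cx,
    }
    side = min(dists, key=dists.get)
    k = _SIDE_TO_ROT90[side]
    fine = estimate_fine_rotation(np.rot90(mask, k).astype(float), max_deg=fine_max_deg)
    return Localization(mask=mask, rot90=k, fine_deg=fine, threshold=float(t))


def align_and_crop(
    img: RawImage, loc: Localization, margin_frac: float = 0.02
) -> tuple[np.ndarray, dict]:
    """Rotate the phantom to bottom-center and crop to its bounding box
    plus a small margin, discarding borders/text/black margins."""
    pix = np.asarray(img.pixels, dtype=float)
    mask = loc.mask
    if loc.rot90 % 4:
        pix = np.rot90(pix, loc.rot90)
        mask = np.rot90(mask, loc.rot90)
    if abs(loc.fine_deg) > 1e-6:
        cval = float(np.median(pix[~mask])) if (~mask).any() else float(pix.min())
        pix = ndimage.rotate(
            pix, loc.fine_deg, reshape=False, order=1, mode="constant", cval=cval
        )
        mask = (
            ndimage.rotate(
                mask.astype(float), loc.fine_deg, reshape=False, order=1,
                mode="constant", cval=0.0,
            )
            > 0.5
        )
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise StageError("align_and_crop", "empty mask after rotation")
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    my = int(round(margin_frac * (y1 - y0)))
    mx = int(round(margin_frac * (x1 - x0)))
    y0, y1 = max(0, y0 - my), min(pix.shape[0], y1 + my)
    x0, x1 = max(0, x0 - mx), min(pix.shape[1], x1 + mx)
    if y1 - y0 < 16 or x1 - x0 < 16:
        raise StageError("align_and_crop", "degenerate crop box")
    prov = {"crop_box": (int(y0), int(x0), int(y1), int(x1)),
            "rotation_deg": 90.0 * loc.rot90 + loc.fine_deg}
    return pix[y0:y1, x0:x1], prov


# ---------------------------------------------------------------------------
# stage 3: lesion-area cropping


def _profile_edges(profile: np.ndarray, margin: int) -> tuple[int, int, float]:
    """Candidate (lo, hi) edge indices from a 1D intensity profile:
    strongest rising edge in the first part, strongest falling edge in
    the last.  Returns edge strength (min of the two |gradients|)."""
    sm = ndimage.gaussian_filter1d(profile, 1.5)
    grad = np.gradient(sm)
    n = len(profile)
    a, b = margin, int(0.45 * n)
    c, d = int(0.55 * n), n - margin
    if b <= a or d <= c:
        return 0, n, 0.0
    lo = a + int(np.argmax(grad[a:b]))
    hi = c + int(np.argmin(grad[c:d]))
    strength = float(min(grad[lo], -grad[hi]))
    return lo, hi, strength


def crop_lesion_area(
    cropped: np.ndarray,
    residual_max_deg: float = 2.5,
    min_insert_contrast: float = 0.015,
) -> tuple[np.ndarray, dict]:
    """Isolate the wax-insert region containing the 4x4 lesion grid.

    The insert border is found from row/column line profiles (the
    insert sits a step brighter than the surrounding block).  A
    residual rotation of up to ``residual_max_deg`` is corrected first.
    If no convincing insert step exists — e.g. the input is already
    insert-only — the full frame is kept.
    """
    pix = np.asarray(cropped, dtype=float)
    if pix.ndim != 2 or min(pix.shape) < 32:
        raise StageError("crop_lesion_area", "input too small")
    work = _rescale01(pix)
    angle = estimate_fine_rotation(work, max_deg=residual_max_deg, downsample=2)
    if abs(angle) > 1e-6:
        pix = ndimage.rotate(
            pix, angle, reshape=False, order=1, mode="nearest"
        )
        work = _rescale01(pix)

    h, w = work.shape
    my, mx = max(3, int(0.06 * h)), max(3, int(0.06 * w))
    x0, x1, sx = _profile_edges(work.mean(axis=0), mx)
    y0, y1, sy = _profile_edges(work.mean(axis=1), my)

    def insert_step_ok() -> bool:
        # accept only if the candidate interior is brighter than the
        # band just outside it (the insert step); otherwise the frame
        # is already insert-only and the full image is kept
        if y1 - y0 < 16 or x1 - x0 < 16:
            return False
        pad_y, pad_x = (y1 - y0) // 8, (x1 - x0) // 8
        inner = work[y0 + pad_y : y1 - pad_y, x0 + pad_x : x1 - pad_x]
        ring = []
        if y0 - pad_y > 0:
            ring.append(work[max(0, y0 - pad_y) : y0, x0:x1].ravel())
        if y1 + pad_y < h:
            ring.append(work[y1 : y1 + pad_y, x0:x1].ravel())
        if x0 - pad_x > 0:
            ring.append(work[y0:y1, max(0, x0 - pad_x) : x0].ravel())
        if x1 + pad_x < w:
            ring.append(work[y0:y1, x1 : x1 + pad_x].ravel())
        if not ring:
            return False
        ring = np.concatenate(ring)
        return float(np.median(inner) - np.median(ring)) > min_insert_contrast

    if not (sx > 0 and sy > 0 and insert_step_ok()):
        y0, x0, y1, x1 = 0, 0, h, w  # already insert-only
    area = pix[y0:y1, x0:x1]
    if area.size == 0:
        raise StageError("crop_lesion_area", "no detectable insert region")
    prov = {"insert_box": (int(y0), int(x0), int(y1), int(x1)),
            "residual_rotation_deg": angle}
    return area, prov


# ---------------------------------------------------------------------------
# stage 4: normalization, resize, grid division


def rhombus_mask(shape: tuple[int, int]) -> np.ndarray:
    """Diamond with vertices at the edge midpoints of the frame."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return np.abs(yy - cy) / (h / 2.0) + np.abs(xx - cx) / (w / 2.0) <= 1.0


def normalize_and_resize(area: np.ndarray) -> StandardizedImage:
    """Window the intensities by the central-rhombus min/max, clip to
    [0, 1] and resize to 224x224 (bilinear).

    Taking the window inside the rhombus makes bright outliers near the
    corners (disc marker, residual text) clip instead of compressing
    the lesion contrast.
    """
    pix = np.asarray(area, dtype=float)
    if pix.ndim != 2 or min(pix.shape) < 8:
        raise StageError("normalize_and_resize", "degenerate lesion-area image")
    rh = rhombus_mask(pix.shape)
    mn, mx = float(pix[rh].min()), float(pix[rh].max())
    if mx - mn < 1e-9:
        raise StageError("normalize_and_resize", "flat image inside rhombus")
    out = np.clip((pix - mn) / (mx - mn), 0.0, 1.0)
    if out.shape != (STD_SIZE, STD_SIZE):
        out = transform.resize(
            out, (STD_SIZE, STD_SIZE), order=1, mode="edge",
            anti_aliasing=min(out.shape) > STD_SIZE, preserve_range=True,
        )
        out = np.clip(out, 0.0, 1.0)
    return StandardizedImage(out, provenance={"window": (mn, mx)})


def split_grid(
    std: StandardizedImage, layout: GridLayout = DEFAULT_LAYOUT
) -> list[Subimage]:
    """Partition a standardized image into its 16 lesion tiles,
    row-major, with lesion type and rank attached from the layout."""
    tiles = []
    for cell in range(16):
        row, col = divmod(cell, 4)
        t, rank = layout.lesion_at(cell)
        block = std.pixels[
            row * TILE_SIZE : (row + 1) * TILE_SIZE,
            col * TILE_SIZE : (col + 1) * TILE_SIZE,
        ]
        tiles.append(Subimage(block, lesion_type=t, rank=rank, grid_cell=cell + 1))
    return tiles


# ---------------------------------------------------------------------------
# composition


def run_pipeline(
    img: RawImage,
    margin_frac: float = 0.02,
    layout: GridLayout = DEFAULT_LAYOUT,
) -> StandardizedImage | PipelineFailure:
    """Full standardization; returns a failure report naming the stage
    that rejected the image instead of raising."""
    try:
        mono = to_monochrome2(img)
        loc = locate_phantom(mono)
        cropped, prov2 = align_and_crop(mono, loc, margin_frac=margin_frac)
        area, prov3 = crop_lesion_area(cropped)
        std = normalize_and_resize(area)
    except StageError as e:
        return PipelineFailure(stage=e.stage, message=e.message)
    std.provenance.update(prov2)
    std.provenance.update(prov3)
    return std


class PhantomStandardizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer over the standardization
    pipeline: ``transform`` maps raw images to standardized images or
    :class:`PipelineFailure` reports."""

    def __init__(self, margin_frac: float = 0.02, layout: GridLayout = DEFAULT_LAYOUT):
        self.margin_frac = margin_frac
        self.layout = layout

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return [
            run_pipeline(img, margin_frac=self.margin_frac, layout=self.layout)
            for img in X
        ]

    def transform_tiles(self, X):
        """Standardize and split; failures pass through as reports."""
        out = []
        for res in self.transform(X):
            if isinstance(res, PipelineFailure):
                out.append(res)
            else:
                out.append(split_grid(res, self.layout))
        return out
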