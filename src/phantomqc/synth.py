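"""Synthetic ACR-style phantom renderer with known ground truth.

Renders stylized mammography accreditation phantom radiographs: an
acrylic block containing a square wax insert with the 4x4 lesion grid
(six fibers, five speck groups of six specks, five masses of decreasing
size and contrast), plus optional disc / text artifacts, under
configurable blur, noise, polarity and orientation.  Because every
lesion's visibility parameters are known, the guideline score of every
cell — and hence the phantom verdict — is known exactly, which makes
the whole downstream pipeline testable without any real data.

Geometry is stylized, not metrologically faithful to any commercial
phantom model: the accepted models' physical dimensions are not public
in a usable form, and nothing downstream depends on absolute scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .images import MONOCHROME1, MONOCHROME2, RawImage, StandardizedImage, Subimage
from .layout import DEFAULT_LAYOUT, FIBER, MASS, SPECKS, GridLayout
from .scores import DEFAULT_POLICY, Score, ScorePolicy

#: relative width of a rendered fiber break (fraction of full length)
BREAK_GAP = 0.08
#: minimum absolute break width in pixels, so short fibers still show
#: a resolvable gap after blurring and resampling
MIN_BREAK_PX = 6.0


def effective_break_gap(size_px: float) -> float:
    """Relative break-gap width for a fiber of ``size_px`` length."""
    return max(BREAK_GAP, MIN_BREAK_PX / max(size_px, 1e-9))

# canvas geometry, as fractions of canvas_size
_PHANTOM_W = 0.74
_PHANTOM_H = 0.60
_BOTTOM_MARGIN = 0.05
_INSERT_SIDE = 0.52
_AIR_LEVEL = 0.04
_INSERT_DELTA = 0.06


@dataclass
class LesionParams:
    """Generative parameters of a single lesion.

    ``visibility`` is a scalar fraction for fibers (rendered length
    fraction, centered) and masses (circular fraction of the contour),
    and a length-6 per-speck opacity vector for speck groups.
    ``break_positions`` lists fractional positions along a fiber where
    gaps are rendered.
    """

    lesion_type: str
    rank: int
    size: float  # length / diameter, pixels (in the rendered cell)
    contrast: float  # peak intensity delta above insert background
    visibility: float | np.ndarray = 1.0
    break_positions: tuple[float, ...] = ()

    def __post_init__(self):
        if self.lesion_type not in (FIBER, SPECKS, MASS):
            raise ValueError(f"invalid lesion type {self.lesion_type!r}")
        nmax = 6 if self.lesion_type == FIBER else 5
        if not 1 <= self.rank <= nmax:
            raise ValueError(f"rank {self.rank} out of range for {self.lesion_type}")
        if self.lesion_type == SPECKS:
            v = np.asarray(self.visibility, dtype=float)
            if v.shape == ():
                v = np.full(6, float(v))
            if v.shape != (6,):
                raise ValueError("speck visibility must be a length-6 vector")
            if v.min() < 0 or v.max() > 1:
                raise ValueError("speck opacities must lie in [0, 1]")
            self.visibility = v
        else:
            v = float(self.visibility)
            if not 0.0 <= v <= 1.0:
                raise ValueError("visibility must lie in [0, 1]")
            self.visibility = v
        if self.lesion_type != FIBER and self.break_positions:
            raise ValueError("break_positions apply to fibers only")
        for b in self.break_positions:
            if not 0.0 < b < 1.0:
                raise ValueError("break positions must lie in (0, 1)")
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")


@dataclass
class Orientation:
    """Orientation perturbation applied to the rendered canvas."""

    rot90: int = 0  # number of 90-degree CCW rotations
    fine_deg: float = 0.0  # additional small CCW rotation
    shift: tuple[float, float] = (0.0, 0.0)  # (dy, dx) pixels


@dataclass
class PhantomSpec:
    """Everything needed to render one phantom deterministically."""

    lesions: list[LesionParams]
    background_level: float = 0.50
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    artifacts: dict = field(
        default_factory=lambda: {"disc": True, "text": True, "border": False}
    )
    photometric: str = MONOCHROME2
    orientation: Orientation = field(default_factory=Orientation)
    canvas_size: int = 512
    seed: int = 0
    layout: GridLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    policy: ScorePolicy = field(default_factory=lambda: DEFAULT_POLICY)

    def __post_init__(self):
        if len(self.lesions) != 16:
            raise ValueError("a phantom spec needs exactly 16 lesions")
        counts = {FIBER: 0, SPECKS: 0, MASS: 0}
        for p in self.lesions:
            counts[p.lesion_type] += 1
        if counts != {FIBER: 6, SPECKS: 5, MASS: 5}:
            raise ValueError(f"need 6 fibers, 5 speck groups, 5 masses; got {counts}")
        if self.canvas_size < 128:
            raise ValueError("canvas too small to contain the phantom")
        dy, dx = self.orientation.shift
        if max(abs(dy), abs(dx)) > 0.08 * self.canvas_size:
            raise ValueError("shift would push the phantom off-canvas")


@dataclass
class GroundTruth:
    """Guideline scores per cell (row-major) and the phantom verdict."""

    scores: list[Score]
    qualified: bool


@dataclass
class RenderResult:
    image: RawImage
    truth: GroundTruth
    #: geometry bookkeeping in the *pre-orientation* canvas frame:
    #: phantom_box / insert_box as (y0, x0, y1, x1), lesion_centroids as
    #: 16 (y, x) pairs, cell size in pixels, applied orientation
    info: dict
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# ground-truth scoring from parameters


def fiber_visible_intervals(
    visibility: float, break_positions: tuple[float, ...], gap: float = BREAK_GAP
) -> list[tuple[float, float]]:
    """Visible sub-intervals of [0, 1] along the fiber axis.

    The rendered portion is the centered fraction ``visibility`` of the
    full length, minus a gap of relative width ``gap`` around each
    break position.
    """
    lo = (1.0 - visibility) / 2.0
    hi = (1.0 + visibility) / 2.0
    if visibility <= 0:
        return []
    segments = [(lo, hi)]
    for b in sorted(break_positions):
        blo, bhi = b - gap / 2.0, b + gap / 2.0
        nxt = []
        for s0, s1 in segments:
            if bhi <= s0 or blo >= s1:
                nxt.append((s0, s1))
                continue
            if blo > s0:
                nxt.append((s0, blo))
            if bhi < s1:
                nxt.append((bhi, s1))
        segments = nxt
    return [(s0, s1) for s0, s1 in segments if s1 - s0 > 1e-9]


def fiber_longest_run(
    visibility: float, break_positions: tuple[float, ...], gap: float = BREAK_GAP
) -> float:
    """Longest continuous visible fraction of the fiber."""
    segs = fiber_visible_intervals(visibility, break_positions, gap)
    return max((s1 - s0 for s0, s1 in segs), default=0.0)


def derive_guideline_score(
    p: LesionParams, policy: ScorePolicy = DEFAULT_POLICY
) -> Score:
    """Apply the guideline rules to the generative parameters.

    Fibers: 1.0 only when the whole fiber is rendered without breaks;
    0.5 when the longest continuous fraction exceeds half; N/A in the
    configured sub-half band.  Speck groups: count of specks whose
    opacity clears the detectability floor; >=5 gives 1.0, 2-3 give 0.5
    (4 per policy).  Masses: present iff contrast clears the floor;
    circular contour fraction > 3/4 gives 1.0, else 0.5.
    """
    if p.lesion_type == FIBER:
        gap = effective_break_gap(p.size)
        run = fiber_longest_run(p.visibility, p.break_positions, gap)
        full = p.visibility >= 1.0 and not p.break_positions
        return policy.score_fiber_fraction(run, full, p.contrast)
    if p.lesion_type == SPECKS:
        count = int(np.sum(np.asarray(p.visibility) >= policy.speck_floor))
        return policy.score_speck_count(count)
    # mass
    return policy.score_mass(p.contrast, p.visibility)


# ---------------------------------------------------------------------------
# rendering


def _soft(x: np.ndarray, aa: float = 1.0) -> np.ndarray:
    """Soft edge profile: 0 below -aa/2, 1 above +aa/2."""
    return np.clip(x / aa + 0.5, 0.0, 1.0)


def _draw_fiber(patch, yy, xx, p: LesionParams, angle_deg: float):
    c = patch.shape[0]
    cy = cx = (c - 1) / 2.0
    th = np.deg2rad(angle_deg)
    dy, dx = np.sin(th), np.cos(th)
    length = p.size
    s = (yy - cy) * dy + (xx - cx) * dx  # along-axis signed distance
    d = np.abs(-(yy - cy) * dx + (xx - cx) * dy)  # perpendicular distance
    frac = s / length + 0.5
    width = max(1.6, 0.055 * c)
    lateral = _soft(width / 2.0 - d)
    cov = np.zeros_like(patch)
    gap = effective_break_gap(length)
    for lo, hi in fiber_visible_intervals(p.visibility, p.break_positions, gap):
        seg = _soft((frac - lo) * length) * _soft((hi - frac) * length)
        np.maximum(cov, seg, out=cov)
    patch += p.contrast * lateral * cov


def _draw_specks(patch, yy, xx, p: LesionParams, offsets):
    c = patch.shape[0]
    cy = cx = (c - 1) / 2.0
    r = p.size / 2.0
    for (oy, ox), opacity in zip(offsets, np.asarray(p.visibility)):
        if opacity <= 0:
            continue
        py, px = cy + oy * c, cx + ox * c
        d = np.hypot(yy - py, xx - px)
        patch += opacity * p.contrast * _soft(r - d)


def _draw_mass(patch, yy, xx, p: LesionParams):
    c = patch.shape[0]
    cy = cx = (c - 1) / 2.0
    radius = p.size / 2.0
    if p.contrast <= 0:
        return
    # disc union centered square; half-width chosen so the circular
    # fraction of the contour equals the visibility parameter exactly
    s = radius * np.cos(p.visibility * np.pi / 4.0)
    d = np.hypot(yy - cy, xx - cx)
    disc = _soft(radius - d)
    square = _soft(s - np.abs(yy - cy)) * _soft(s - np.abs(xx - cx))
    patch += p.contrast * np.maximum(disc, square)


def _render_base(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Render the unrotated, noiseless-orientation canvas and geometry."""
    n = spec.canvas_size
    img = np.full((n, n), _AIR_LEVEL, dtype=float)

    pw, ph = int(_PHANTOM_W * n), int(_PHANTOM_H * n)
    py1 = n - int(_BOTTOM_MARGIN * n)
    py0 = py1 - ph
    px0 = (n - pw) // 2
    px1 = px0 + pw
    img[py0:py1, px0:px1] = spec.background_level

    side = int(_INSERT_SIDE * n)
    side -= side % 4  # integral cell size
    iy0 = py0 + (ph - side) * 2 // 3  # a little below phantom center
    ix0 = px0 + (pw - side) // 2
    iy1, ix1 = iy0 + side, ix0 + side
    img[iy0:iy1, ix0:ix1] = spec.background_level + _INSERT_DELTA

    cell = side // 4
    centroids = []
    for idx, p in enumerate(spec.lesions):
        row, col = divmod(idx, 4)
        y0, x0 = iy0 + row * cell, ix0 + col * cell
        patch = img[y0 : y0 + cell, x0 : x0 + cell]
        yy, xx = np.mgrid[0:cell, 0:cell].astype(float)
        if p.lesion_type == FIBER:
            _draw_fiber(patch, yy, xx, p, spec.layout.fiber_angle_deg)
        elif p.lesion_type == SPECKS:
            _draw_specks(patch, yy, xx, p, spec.layout.speck_offsets)
        else:
            _draw_mass(patch, yy, xx, p)
        centroids.append((y0 + (cell - 1) / 2.0, x0 + (cell - 1) / 2.0))

    if spec.artifacts.get("disc", False):
        # bright acrylic disc at the top-right corner of the insert,
        # away from every lesion but inside the lesion-area crop: the
        # outlier the rhombus window is designed to ignore
        r = max(3.0, 0.040 * side)
        cy, cx = iy0 + 0.04 * side, ix0 + 0.96 * side
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        img += 0.45 * _soft(r - np.hypot(yy - cy, xx - cx))
    if spec.artifacts.get("text", False):
        # stylized ID text: small bright ticks above the phantom (air)
        # and inside the phantom margin above the insert
        rng = np.random.default_rng(spec.seed + 12345)
        ty = max(2, py0 // 3)
        for k in range(8):
            tx = px0 + 10 + 11 * k + int(rng.integers(0, 3))
            img[ty : ty + 8, tx : tx + 6] = 0.9
        my = (py0 + iy0) // 2
        for k in range(5):
            tx = ix0 + 14 * k
            img[my : my + 5, tx : tx + 8] = spec.background_level + 0.3
    if spec.artifacts.get("border", False):
        w = max(3, n // 90)
        img[:w, :] = 0.95
        img[-w:, :] = 0.95
        img[:, :w] = 0.95
        img[:, -w:] = 0.95

    info = {
        "phantom_box": (py0, px0, py1, px1),
        "insert_box": (iy0, ix0, iy1, ix1),
        "cell_size": cell,
        "lesion_centroids": centroids,
        "canvas_size": n,
    }
    return img, info


def render_phantom(spec: PhantomSpec) -> RenderResult:
    """Render a phantom radiograph and its ground truth.

    Deterministic for a fixed spec (the spec's ``seed`` drives the
    noise).  Monochrome1 output is the pixelwise complement of the
    monochrome2 render.
    """
    img, info = _render_base(spec)

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    o = spec.orientation
    if o.fine_deg:
        img = ndimage.rotate(
            img, o.fine_deg, reshape=False, order=1, mode="constant", cval=_AIR_LEVEL
        )
    if any(o.shift):
        img = ndimage.shift(img, o.shift, order=1, mode="constant", cval=_AIR_LEVEL)
    if o.rot90 % 4:
        img = np.rot90(img, o.rot90 % 4)
    np.clip(img, 0.0, 1.0, out=img)

    if spec.photometric == MONOCHROME1:
        img = 1.0 - img

    info = dict(info, orientation=dataclasses.asdict(o))
    scores = [derive_guideline_score(p, spec.policy) for p in spec.lesions]
    from .qualify import qualify_phantom  # local import to avoid cycle at import time

    truth = GroundTruth(
        scores=scores,
        qualified=qualify_phantom(scores, spec.layout).qualified,
    )
    raw = RawImage(img, photometric=spec.photometric, bit_depth=16)
    return RenderResult(image=raw, truth=truth, info=info, spec=spec)


def standardize_exact(result: RenderResult) -> StandardizedImage:
    """Standardize a render using the generator's exact insert box.

    A fast path for producing training tiles: bypasses localization
    (which is tested separately) by cropping the known insert region,
    then applying the same rhombus normalization and resize as the
    preprocessing pipeline.  Requires an unrotated monochrome2 render.
    """
    o = result.spec.orientation
    if o.rot90 % 4 or o.fine_deg or any(o.shift):
        raise ValueError("exact standardization requires an unrotated render")
    pix = result.image.pixels
    if result.spec.photometric == MONOCHROME1:
        pix = 1.0 - pix
    iy0, ix0, iy1, ix1 = result.info["insert_box"]
    from .preprocess import normalize_and_resize

    return normalize_and_resize(pix[iy0:iy1, ix0:ix1])


def render_subimages(spec: PhantomSpec) -> tuple[list[Subimage], GroundTruth]:
    """Render a phantom and return its 16 standardized tiles + truth."""
    spec = replace(spec, orientation=Orientation(), photometric=MONOCHROME2)
    result = render_phantom(spec)
    std = standardize_exact(result)
    from .preprocess import split_grid

    return split_grid(std, spec.layout), result.truth


# ---------------------------------------------------------------------------
# sampling


def nominal_lesions(layout: GridLayout = DEFAULT_LAYOUT, cell: int = 66
                    ) -> list[LesionParams]:
    """Fully visible lesion set for a given rendered cell size."""
    out = []
    for t, rank in layout.cell_map:
        vis = np.ones(6) if t == SPECKS else 1.0
        out.append(
            LesionParams(
                lesion_type=t,
                rank=rank,
                size=layout.size_frac(t, rank) * cell,
                contrast=layout.contrast(t, rank),
                visibility=vis,
            )
        )
    return out


#: quality modes: per-rank probability of a full (1.0) score, and how
#: the remaining mass splits over half / zero / N/A.  Large lesions
#: fail rarely even on degraded images; small ones fail first — the
#: rank trend real corpora show.
_GOOD_MODE = {
    FIBER: {"full_by_rank": (0.99, 0.985, 0.975, 0.955, 0.90, 0.82),
            "nonfull": {"half": 0.60, "zero": 0.15, "na": 0.25}},
    SPECKS: {"full_by_rank": (0.99, 0.975, 0.95, 0.88, 0.78),
             "nonfull": {"half": 0.25, "zero": 0.75, "na": 0.0}},
    MASS: {"full_by_rank": (0.99, 0.975, 0.95, 0.85, 0.72),
           "nonfull": {"half": 0.80, "zero": 0.20, "na": 0.0}},
}
_DEGRADED_MODE = {
    FIBER: {"full_by_rank": (0.72, 0.62, 0.52, 0.42, 0.30, 0.20),
            "nonfull": {"half": 0.50, "zero": 0.30, "na": 0.20}},
    SPECKS: {"full_by_rank": (0.70, 0.58, 0.45, 0.32, 0.22),
             "nonfull": {"half": 0.20, "zero": 0.80, "na": 0.0}},
    MASS: {"full_by_rank": (0.68, 0.55, 0.42, 0.30, 0.20),
           "nonfull": {"half": 0.70, "zero": 0.30, "na": 0.0}},
}


@dataclass
class SamplingConfig:
    """Sampling law for random phantom datasets.

    Image quality is correlated across the lesions of one phantom (a
    well-exposed image shows nearly everything; a degraded one loses
    lesions of every type), so phantoms are drawn from a two-mode
    quality mixture.  The default mode weights and per-mode class
    probabilities are chosen so the *marginal* per-lesion score
    distribution matches the one reported for the national QA corpus
    (roughly 80/12/8 full/half/zero for fibers, 79/4/18 for speck
    groups, 75/20/5 for masses).  ``class_probs`` overrides the
    mixture with a single explicit per-lesion law.

    Visibility values within a class are drawn from bands that sit
    clear of the guideline decision boundaries: real phantom lesions
    are either plainly visible, plainly partial, or plainly absent at
    these stylized contrasts, and boundary behaviour is exercised by
    deterministic sweeps instead.
    """

    modes: tuple = field(
        default_factory=lambda: ((0.72, _GOOD_MODE), (0.28, _DEGRADED_MODE))
    )
    class_probs: dict | None = None
    noise_sigma: tuple[float, float] = (0.004, 0.016)
    blur_sigma: tuple[float, float] = (0.4, 0.9)
    background_level: tuple[float, float] = (0.46, 0.54)
    fine_rotation_deg: tuple[float, float] = (-1.5, 1.5)
    shift_frac: tuple[float, float] = (-0.015, 0.015)
    rot90_choices: tuple[int, ...] = (0,)
    artifact_prob: float = 0.8
    canvas_size: int = 512

    @classmethod
    def easy(cls) -> "SamplingConfig":
        """Low-noise, well-aligned conditions for desk-scale training."""
        return cls(
            noise_sigma=(0.002, 0.008),
            blur_sigma=(0.3, 0.6),
            fine_rotation_deg=(0.0, 0.0),
            shift_frac=(0.0, 0.0),
            artifact_prob=0.5,
        )


def _sample_fiber(rng, rank, layout, cell, cls) -> LesionParams:
    size = layout.size_frac(FIBER, rank) * cell
    contrast = layout.contrast(FIBER, rank)
    if cls == "full":
        return LesionParams(FIBER, rank, size, contrast, 1.0)
    if cls == "half":
        target = rng.uniform(0.58, 0.88)
        if rng.random() < 0.5:
            return LesionParams(FIBER, rank, size, contrast, target)
        # full-length fiber with one break so the longest run == target
        gap = effective_break_gap(size)
        b = min(target + gap / 2.0, 1.0 - gap / 2.0 - 1e-3)
        return LesionParams(FIBER, rank, size, contrast, 1.0, (float(b),))
    if cls == "na":
        return LesionParams(FIBER, rank, size, contrast, rng.uniform(0.18, 0.44))
    return LesionParams(FIBER, rank, size, contrast, 0.0)


def _sample_specks(rng, rank, layout, cell, cls) -> LesionParams:
    size = layout.size_frac(SPECKS, rank) * cell
    contrast = layout.contrast(SPECKS, rank)
    k = {"full": rng.integers(5, 7), "half": rng.integers(2, 4),
         "zero": rng.integers(0, 2), "na": 1}[cls]
    op = np.zeros(6)
    on = rng.choice(6, size=int(k), replace=False)
    op[on] = rng.uniform(0.6, 1.0, size=int(k))
    off = np.setdiff1d(np.arange(6), on)
    op[off] = rng.uniform(0.0, 0.05, size=off.size)
    return LesionParams(SPECKS, rank, size, contrast, op)


def _sample_mass(rng, rank, layout, cell, cls) -> LesionParams:
    size = layout.size_frac(MASS, rank) * cell
    contrast = layout.contrast(MASS, rank)
    if cls == "full":
        return LesionParams(MASS, rank, size, contrast, rng.uniform(0.86, 1.0))
    if cls == "half":
        return LesionParams(MASS, rank, size, contrast, rng.uniform(0.20, 0.55))
    if cls == "na":
        policy = DEFAULT_POLICY
        c = 0.7 * policy.mass_contrast_floor
        return LesionParams(MASS, rank, size, c, 1.0)
    return LesionParams(MASS, rank, size, 0.0, 1.0)


_SAMPLERS = {FIBER: _sample_fiber, SPECKS: _sample_specks, MASS: _sample_mass}


def sample_spec(
    rng: np.random.Generator,
    config: SamplingConfig | None = None,
    layout: GridLayout = DEFAULT_LAYOUT,
) -> PhantomSpec:
    """Draw one random phantom spec from the sampling law."""
    config = config or SamplingConfig()
    n = config.canvas_size
    side = int(_INSERT_SIDE * n)
    cell = (side - side % 4) // 4
    if config.class_probs is not None:
        mode = None
    else:
        weights = np.array([w for w, _ in config.modes], dtype=float)
        mode = config.modes[rng.choice(len(config.modes), p=weights / weights.sum())][1]
    lesions = []
    for t, rank in layout.cell_map:
        if mode is None:
            probs = dict(config.class_probs[t])
        else:
            p_full = mode[t]["full_by_rank"][rank - 1]
            split = mode[t]["nonfull"]
            probs = {"full": p_full}
            for cls_name in ("half", "zero", "na"):
                probs[cls_name] = (1.0 - p_full) * split.get(cls_name, 0.0)
        classes = list(probs)
        p = np.array([probs[c] for c in classes], dtype=float)
        cls = rng.choice(classes, p=p / p.sum())
        lesions.append(_SAMPLERS[t](rng, rank, layout, cell, cls))
    art = rng.random() < config.artifact_prob
    return PhantomSpec(
        lesions=lesions,
        background_level=rng.uniform(*config.background_level),
        noise_sigma=rng.uniform(*config.noise_sigma),
        blur_sigma=rng.uniform(*config.blur_sigma),
        artifacts={"disc": art, "text": art, "border": False},
        orientation=Orientation(
            rot90=int(rng.choice(config.rot90_choices)),
            fine_deg=rng.uniform(*config.fine_rotation_deg),
            shift=(
                rng.uniform(*config.shift_frac) * n,
                rng.uniform(*config.shift_frac) * n,
            ),
        ),
        canvas_size=n,
        seed=int(rng.integers(0, 2**31 - 1)),
        layout=layout,
    )


def sample_dataset(
    n: int,
    config: SamplingConfig | None = None,
    seed: int = 0,
    layout: GridLayout = DEFAULT_LAYOUT,
) -> list[RenderResult]:
    """Render ``n`` random phantoms reproducibly.

    The per-lesion score-class frequencies follow the sampling law in
    ``config`` so class imbalance can be imitated or overridden.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [render_phantom(sample_spec(rng, config, layout)) for _ in range(n)]
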