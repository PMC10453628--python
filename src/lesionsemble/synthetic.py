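"""Synthetic dermoscopy-like images with exact ground truth.

Real dermoscopic lesion images are confounded by hair strokes, ink markers,
smooth illumination (intensity-inhomogeneity) gradients, low lesion/skin
contrast and blurred boundaries.  This module draws elliptical dark lesions
on a lighter skin background and overlays those artefact classes in a fully
seeded, reproducible way, so the whole segmentation pipeline can be exercised
against pixel-exact ground-truth masks without any external dataset.

The ground truth is always the exact ellipse indicator recorded *before* any
artefact is painted; hair, markers and noise degrade only the image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter, line

STRATA = ("clean", "hairy", "inhomogeneous", "low_contrast", "marker")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic lesion image.

    Intensities follow the dark-lesion-on-light-skin polarity of dermoscopy:
    lesion mean ~60, skin mean ~190 on the 8-bit scale, hair darker still
    (~30).  ``inhomogeneity`` is the relative amplitude of a smooth
    multiplicative illumination field; ``boundary_blur_sigma`` softens the
    lesion edge to emulate ill-defined boundaries.

    ``size`` is the *working* grid on which the ground-truth mask is defined.
    The image itself is rendered at ``supersample`` times that resolution —
    real dermoscopic frames are far larger than the segmentation grid, and
    rendering artefacts at native scale keeps their width realistic: a 2-px
    hair on the rendered frame stays hair-thin after the pipeline resizes,
    instead of becoming a rope several working-pixels wide.  Geometry,
    ``hair_thickness`` and the marker rim are expressed in rendered pixels.
    """

    size: tuple[int, int] = (56, 56)
    center: tuple[float, float] | None = None  # None -> image centre
    axes: tuple[float, float] = (14.0, 10.0)   # ellipse semi-axes (rows, cols)
    rotation: float = 0.0                      # radians
    lesion_mean: float = 60.0
    lesion_sd: float = 6.0
    skin_mean: float = 190.0
    skin_sd: float = 6.0
    hair_count: int = 0
    hair_thickness: int = 2
    hair_intensity: float = 30.0
    inhomogeneity: float = 0.0
    inhomogeneity_kind: str = "planar"         # "planar" | "radial"
    marker: bool = False
    boundary_blur_sigma: float = 0.0
    noise_sd: float = 4.0
    seed: int = 0
    allow_edge: bool = False
    supersample: int = 4


@dataclass
class Fixture:
    """A generated image plus its exact ground truth."""

    image: np.ndarray   # float64 in [0, 255]
    mask: np.ndarray    # uint8 {0, 1}, exact ellipse indicator
    spec: FixtureSpec
    stratum: str = "clean"
    fixture_id: str = ""


def _ellipse_mask(spec: FixtureSpec, scale: int = 1) -> np.ndarray:
    """Ellipse indicator sampled on the working grid blown up by ``scale``.

    Geometry is expressed in working-grid coordinates; rendered pixel r sits
    at working position (r + 0.5) / scale - 0.5, matching the corner-aligned
    convention of the bilinear resize used downstream.
    """
    h, w = spec.size
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    a, b = spec.axes
    ys = (np.arange(h * scale) + 0.5) / scale - 0.5
    xs = (np.arange(w * scale) + 0.5) / scale - 0.5
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    cos_t, sin_t = np.cos(spec.rotation), np.sin(spec.rotation)
    u = dy * cos_t + dx * sin_t
    v = -dy * sin_t + dx * cos_t
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _draw_hair(
    img: np.ndarray, rng: np.random.Generator, spec: FixtureSpec, scale: int
) -> None:
    h, w = img.shape
    kink = 6 * scale
    for _ in range(spec.hair_count):
        # random chord across the image, slightly curved via a midpoint kink
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        r1, c1 = rng.integers(0, h), rng.integers(0, w)
        rm = (r0 + r1) // 2 + rng.integers(-kink, kink + 1)
        cm = (c0 + c1) // 2 + rng.integers(-kink, kink + 1)
        canvas = np.zeros((h, w), dtype=bool)
        for (ra, ca), (rb, cb) in (((r0, c0), (rm, cm)), ((rm, cm), (r1, c1))):
            rr, cc = line(int(np.clip(ra, 0, h - 1)), int(np.clip(ca, 0, w - 1)),
                          int(np.clip(rb, 0, h - 1)), int(np.clip(cb, 0, w - 1)))
            canvas[rr, cc] = True
        if spec.hair_thickness > 1:
            t = spec.hair_thickness
            canvas = ndimage.binary_dilation(canvas, structure=np.ones((t, t)))
        # soft edge: blend a blurred stroke instead of hard-setting pixels
        weight = ndimage.gaussian_filter(canvas.astype(float), 0.5)
        weight = np.clip(weight * 1.5, 0.0, 1.0)
        img[:] = (1.0 - weight) * img + weight * spec.hair_intensity


def _inhomogeneity_field(
    spec: FixtureSpec, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    a = spec.inhomogeneity
    if spec.inhomogeneity_kind == "radial":
        r = np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0)
        return 1.0 - a * (r / r.max()) ** 2
    theta = rng.uniform(0.0, 2.0 * np.pi)
    proj = (rr / (h - 1)) * np.cos(theta) + (cc / (w - 1)) * np.sin(theta)
    proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
    return 1.0 - a + 2.0 * a * proj


def _draw_marker(img: np.ndarray, rng: np.random.Generator, scale: int) -> None:
    """Bright circular rim, as left by dermoscopy rulers / ink markers."""
    h, w = img.shape
    cy = int(rng.integers(6 * scale, h // 3))
    cx = int(rng.integers(6 * scale, w // 3))
    radius = int(rng.integers(4, 7)) * scale
    for r in range(radius, radius + scale + 1):
        rr, cc = circle_perimeter(cy, cx, r, shape=img.shape)
        img[rr, cc] = 250.0


def generate(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one fixture; deterministic given ``spec.seed``.

    Returns the image (float64 in [0, 255], rendered at ``supersample``
    times the working size) and the exact ground-truth mask on the working
    grid.
    """
    h, w = spec.size
    s = spec.supersample
    if h < 8 or w < 8:
        raise ValueError("image too small")
    if s < 1:
        raise ValueError("supersample must be >= 1")
    if min(spec.axes) <= 0:
        raise ValueError("ellipse axes must be positive")
    truth = _ellipse_mask(spec, scale=1)
    if not truth.any():
        raise ValueError("lesion ellipse lies outside the image")
    if not spec.allow_edge:
        border = np.concatenate([truth[0], truth[-1], truth[:, 0], truth[:, -1]])
        if border.any():
            raise ValueError("lesion ellipse touches the image border")

    rng = np.random.default_rng(spec.seed)
    shape = (h * s, w * s)
    lesion = _ellipse_mask(spec, scale=s)
    img = np.where(lesion == 1, spec.lesion_mean, spec.skin_mean).astype(float)
    img += np.where(
        lesion == 1,
        rng.normal(0.0, spec.lesion_sd, size=shape),
        rng.normal(0.0, spec.skin_sd, size=shape),
    )
    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur_sigma * s)
    if spec.inhomogeneity > 0:
        img *= _inhomogeneity_field(spec, rng, shape)
    if spec.hair_count > 0:
        _draw_hair(img, rng, spec, s)
    if spec.marker:
        _draw_marker(img, rng, s)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    return np.clip(img, 0.0, 255.0), truth


def _stratum_spec(stratum: str, base: FixtureSpec) -> FixtureSpec:
    if stratum == "clean":
        return base
    if stratum == "hairy":
        return replace(base, hair_count=15, hair_thickness=2)
    if stratum == "inhomogeneous":
        # ring-lit dermoscopes vignette radially: borders darken, centre keeps
        return replace(base, inhomogeneity=0.35, inhomogeneity_kind="radial")
    if stratum == "low_contrast":
        return replace(base, lesion_mean=120.0, skin_mean=165.0,
                       boundary_blur_sigma=1.5)
    if stratum == "marker":
        return replace(base, marker=True)
    raise ValueError(f"unknown stratum {stratum!r}")


def generate_suite(
    n: int = 50,
    difficulty_mix: dict[str, float] | None = None,
    seed: int = 0,
    size: tuple[int, int] = (56, 56),
) -> list[Fixture]:
    """Reproducible stratified suite of fixtures.

    ``difficulty_mix`` maps stratum name to its proportion (defaults to an
    even split over the five strata); counts are rounded with remainders
    assigned in stratum order.  Lesion geometry (centre jitter, semi-axes,
    rotation) is randomized per image from the suite seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = difficulty_mix or {s: 1.0 / len(STRATA) for s in STRATA}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("difficulty_mix proportions must sum to 1")
    unknown = set(mix) - set(STRATA)
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}")

    counts = {s: int(np.floor(mix[s] * n)) for s in mix}
    remainder = n - sum(counts.values())
    for s in list(mix):
        if remainder == 0:
            break
        counts[s] += 1
        remainder -= 1

    rng = np.random.default_rng(seed)
    h, w = size
    fixtures: list[Fixture] = []
    idx = 0
    for stratum in STRATA:
        for _ in range(counts.get(stratum, 0)):
            axes = (float(rng.uniform(9.0, 16.0)), float(rng.uniform(7.0, 13.0)))
            margin = max(axes) + 2.0
            cy = float(rng.uniform(margin, h - 1 - margin))
            cx = float(rng.uniform(margin, w - 1 - margin))
            base = FixtureSpec(
                size=size, center=(cy, cx), axes=axes,
                rotation=float(rng.uniform(0.0, np.pi)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            spec = _stratum_spec(stratum, base)
            image, mask = generate(spec)
            fixtures.append(Fixture(
                image=image, mask=mask, spec=spec, stratum=stratum,
                fixture_id=f"synth_{idx:04d}_{stratum}",
            ))
            idx += 1
    return fixtures
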