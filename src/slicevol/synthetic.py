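"""Synthetic fixture generator.

Renders calibrated top-view (and optional side-view) images of parametric
axi-symmetric solids whose volumes are known in closed form, so every
pipeline stage can be validated without real photographs.

A shape is a solid whose visible half-width at axial position ``t`` (cm) is
``a(t)`` and whose cross-sections are ellipses with depth diameter
``2 a(t) / r`` for aspect ratio ``r``; its exact volume is
``(pi / r) * integral(a(t)^2 dt)``, evaluated in closed form per kind.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.special import gamma as gamma_fn

from .estimator import ProductProfile, classify
from .silhouette import CalibratedImage

__all__ = [
    "ShapeSpec",
    "RenderSpec",
    "GroundTruth",
    "SHAPE_KINDS",
    "FRAME_PRESETS",
    "make_shape",
    "render_top_view",
    "render_side_view",
    "make_population",
]

SHAPE_KINDS = (
    "cylinder",
    "cone",
    "ellipsoid",
    "spindle",
    "tapered-carrot",
    "bent-spindle",
)

# (height, width) pixel presets; "full" matches the reference acquisition
# resolution, the smaller two support resolution-degradation experiments
FRAME_PRESETS = {
    "full": (1538, 2175),
    "medium": (1080, 1440),
    "small": (720, 960),
}

DEFAULT_FOREGROUND = (214, 106, 24)  # carrot orange
DEFAULT_BACKGROUND = (245, 245, 245)  # near-white


@dataclass(frozen=True)
class ShapeSpec:
    """A parametric solid of revolution (optionally bent) with known volume."""

    kind: str
    length: float  # cm
    max_width: float  # cm, visible (in-plane) diameter at the widest point
    aspect_ratio: float  # visible width / depth diameter
    params: dict = field(default_factory=dict)
    analytic_volume: float = 0.0  # cm^3, set by make_shape

    def half_width(self, t: np.ndarray) -> np.ndarray:
        """Visible half-width a(t) in cm for axial positions t in [0, L]."""
        t = np.asarray(t, dtype=float)
        u = np.clip(t / self.length, 0.0, 1.0)
        a = self.max_width / 2.0
        if self.kind == "cylinder":
            prof = np.full_like(u, a)
        elif self.kind == "cone":
            prof = a * (1.0 - u)
        elif self.kind == "ellipsoid":
            prof = a * np.sqrt(np.clip(1.0 - (2.0 * u - 1.0) ** 2, 0.0, None))
        elif self.kind in ("spindle", "bent-spindle"):
            q = self.params.get("exponent", 1.0)
            prof = a * np.sin(math.pi * u) ** q
        elif self.kind == "tapered-carrot":
            # rounded (elliptical) shoulder over the first fraction s of the
            # length, then a power-law taper down to the tip
            p = self.params.get("taper_exponent", 0.75)
            s = self.params.get("shoulder_frac", 0.15)
            shoulder = np.sqrt(np.clip(1.0 - ((s - u) / s) ** 2, 0.0, None))
            taper = np.clip(1.0 - (u - s) / (1.0 - s), 0.0, None) ** p
            prof = a * np.where(u < s, shoulder, taper)
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        out = np.where((t < 0) | (t > self.length), 0.0, prof)
        return out


def _profile_square_integral(kind: str, length: float, a: float, params: dict) -> float:
    """Closed-form integral of a(t)^2 over [0, L]."""
    if kind == "cylinder":
        return a * a * length
    if kind == "cone":
        return a * a * length / 3.0
    if kind == "ellipsoid":
        return a * a * length * 2.0 / 3.0
    if kind in ("spindle", "bent-spindle"):
        q = params.get("exponent", 1.0)
        # integral of sin^(2q) over a half period: L * Gamma(q+1/2) / (sqrt(pi) Gamma(q+1))
        return a * a * length * gamma_fn(q + 0.5) / (math.sqrt(math.pi) * gamma_fn(q + 1.0))
    if kind == "tapered-carrot":
        p = params.get("taper_exponent", 0.75)
        s = params.get("shoulder_frac", 0.15)
        return a * a * length * (2.0 * s / 3.0 + (1.0 - s) / (2.0 * p + 1.0))
    raise ValueError(f"unknown shape kind {kind!r}")


def make_shape(
    kind: str,
    length: float,
    max_width: float,
    aspect_ratio: float = 1.0,
    **params,
) -> ShapeSpec:
    """Build a shape with its analytic volume.

    For the bent spindle the centerline follows a circular arc
    (``bend_radius`` cm); because every cross-section's centroid lies on
    the centerline, Pappus's theorem gives the same volume as the straight
    spindle of equal arc length.
    """
    if kind not in SHAPE_KINDS:
        raise ValueError(f"unknown shape kind {kind!r}; choose from {SHAPE_KINDS}")
    if length <= 0 or max_width <= 0 or aspect_ratio <= 0:
        raise ValueError("length, max_width and aspect_ratio must be > 0")
    if kind == "bent-spindle":
        bend_radius = params.setdefault("bend_radius", 2.0 * length)
        if bend_radius <= length / math.pi:
            raise ValueError("bend radius too tight for the arc length")
    volume = (
        math.pi
        / aspect_ratio
        * _profile_square_integral(kind, length, max_width / 2.0, params)
    )
    return ShapeSpec(
        kind=kind,
        length=length,
        max_width=max_width,
        aspect_ratio=aspect_ratio,
        params=dict(params),
        analytic_volume=volume,
    )


@dataclass(frozen=True)
class RenderSpec:
    """How to rasterise a shape into a calibrated image."""

    px_per_cm: float = 70.0
    rotation_deg: float = 0.0
    margin_px: int = 24
    frame_shape: tuple[int, int] | None = None  # (H, W); None -> fit to shape
    noise_sigma_px: float = 0.0  # boundary jitter, std-dev in pixels
    salt_pepper_rate: float = 0.0  # fraction of pixels flipped
    foreground: tuple[int, int, int] = DEFAULT_FOREGROUND
    background: tuple[int, int, int] = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-image analytic reference values."""

    kind: str
    volume_ml: float
    length_cm: float
    max_width_cm: float
    aspect_ratio: float
    mass_g: float | None = None
    class_label: str | None = None
    seed: int | None = None


def _centerline_frame(shape: ShapeSpec, x: np.ndarray, y: np.ndarray):
    """Axial position t and centerline distance for shape-frame coords.

    The straight axis runs along +x from the origin; a bent centerline is a
    circular arc through the origin, initially tangent to +x, curving
    towards +y.
    """
    if shape.kind != "bent-spindle":
        return x, np.abs(y)
    rad = shape.params["bend_radius"]
    # circle center at (0, rad); angle from the downward (-y of center) direction
    dx = x
    dy = y - rad
    dist_c = np.hypot(dx, dy)
    phi = np.arctan2(dx, -dy)  # 0 at origin, grows along the arc
    t = rad * phi
    return t, np.abs(dist_c - rad)


def _shape_extent_cm(shape: ShapeSpec) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of the solid in its own frame, cm."""
    a_max = shape.max_width / 2.0
    if shape.kind != "bent-spindle":
        return 0.0, shape.length, -a_max, a_max
    rad = shape.params["bend_radius"]
    phi_end = shape.length / rad
    phis = np.linspace(0.0, phi_end, 256)
    cx = rad * np.sin(phis)
    cy = rad - rad * np.cos(phis)
    return (
        float(cx.min() - a_max),
        float(cx.max() + a_max),
        float(cy.min() - a_max),
        float(cy.max() + a_max),
    )


def _rasterize(
    shape: ShapeSpec,
    spec: RenderSpec,
    rng: np.random.Generator,
    depth_view: bool = False,
) -> np.ndarray:
    """Binary mask of the rendered silhouette."""
    ppc = spec.px_per_cm
    theta = math.radians(spec.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    xmin, xmax, ymin, ymax = _shape_extent_cm(shape)
    if depth_view:  # side view shows the depth diameter, wider by 1/r
        ymin, ymax = ymin / shape.aspect_ratio, ymax / shape.aspect_ratio
    corners = np.array(
        [[xmin, ymin], [xmin, ymax], [xmax, ymin], [xmax, ymax]], dtype=float
    )
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    rot_corners = corners @ rot.T
    ext_min = rot_corners.min(axis=0)
    ext_max = rot_corners.max(axis=0)

    if spec.frame_shape is None:
        w_px = int(math.ceil((ext_max[0] - ext_min[0]) * ppc)) + 2 * spec.margin_px
        h_px = int(math.ceil((ext_max[1] - ext_min[1]) * ppc)) + 2 * spec.margin_px
    else:
        h_px, w_px = spec.frame_shape
        need_w = (ext_max[0] - ext_min[0]) * ppc + 2 * spec.margin_px
        need_h = (ext_max[1] - ext_min[1]) * ppc + 2 * spec.margin_px
        if need_w > w_px or need_h > h_px:
            raise ValueError("object does not fit in the requested frame")

    # pixel-center coordinates back-rotated into the shape frame
    offset = np.array(
        [
            (w_px / ppc - (ext_max[0] - ext_min[0])) / 2.0 - ext_min[0],
            (h_px / ppc - (ext_max[1] - ext_min[1])) / 2.0 - ext_min[1],
        ]
    )
    cols = (np.arange(w_px) + 0.5) / ppc - offset[0]
    rows = (np.arange(h_px) + 0.5) / ppc - offset[1]
    gx, gy = np.meshgrid(cols, rows)
    sx = cos_t * gx + sin_t * gy
    sy = -sin_t * gx + cos_t * gy

    t, dist = _centerline_frame(shape, sx, sy)
    a = shape.half_width(t)
    if depth_view:
        a = a / shape.aspect_ratio
    if spec.noise_sigma_px > 0:
        # smooth boundary jitter: noise drawn at coarse axial stations and
        # linearly interpolated along t
        n_ctrl = 48
        ctrl_t = np.linspace(0.0, shape.length, n_ctrl)
        ctrl_noise = rng.normal(0.0, spec.noise_sigma_px / ppc, n_ctrl)
        a = a + np.interp(t, ctrl_t, ctrl_noise) * (a > 0)
    return dist <= a


def _paint(mask: np.ndarray, spec: RenderSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.empty(mask.shape + (3,), dtype=np.uint8)
    img[...] = np.asarray(spec.background, dtype=np.uint8)
    img[mask] = np.asarray(spec.foreground, dtype=np.uint8)
    if spec.salt_pepper_rate > 0:
        flip = rng.random(mask.shape) < spec.salt_pepper_rate
        img[flip & mask] = np.asarray(spec.background, dtype=np.uint8)
        img[flip & ~mask] = np.asarray(spec.foreground, dtype=np.uint8)
    return img


def render_top_view(
    shape: ShapeSpec,
    spec: RenderSpec | None = None,
    seed: int = 0,
    density: float | None = None,
    product: ProductProfile | None = None,
    out_path: str | Path | None = None,
) -> tuple[CalibratedImage, GroundTruth]:
    """Render the top view and return the image with its ground truth.

    The silhouette half-width at axial position ``t`` equals
    ``shape.half_width(t) * px_per_cm`` before noise.  With ``out_path`` the
    image is also written as PNG (deterministic bytes for a fixed seed).
    """
    spec = spec or RenderSpec()
    rng = np.random.default_rng(seed)
    mask = _rasterize(shape, spec, rng)
    img = _paint(mask, spec, rng)
    mass = None
    label = None
    if density is not None:
        mass = shape.analytic_volume * density
        if product is not None:
            label = classify(mass, product)
    truth = GroundTruth(
        kind=shape.kind,
        volume_ml=shape.analytic_volume,
        length_cm=shape.length,
        max_width_cm=shape.max_width,
        aspect_ratio=shape.aspect_ratio,
        mass_g=mass,
        class_label=label,
        seed=seed,
    )
    image = CalibratedImage(pixels=img, px_per_cm=spec.px_per_cm)
    if out_path is not None:
        Image.fromarray(img).save(Path(out_path), format="PNG")
    return image, truth


def render_side_view(
    shape: ShapeSpec,
    spec: RenderSpec | None = None,
    seed: int = 0,
    truncate_bottom_frac: float = 0.0,
    out_path: str | Path | None = None,
) -> CalibratedImage:
    """Render the orthogonal side view (width scaled by 1/aspect_ratio).

    ``truncate_bottom_frac`` removes the given fraction of the silhouette's
    thickness on one side, emulating the contact-surface loss of a real
    side-view photograph.
    """
    spec = spec or RenderSpec()
    rng = np.random.default_rng(seed)
    mask = _rasterize(shape, spec, rng, depth_view=True)
    if truncate_bottom_frac > 0:
        rows = np.nonzero(mask.any(axis=1))[0]
        n_cut = int(round(len(rows) * truncate_bottom_frac))
        if n_cut > 0:
            mask[rows[-n_cut:], :] = False
    img = _paint(mask, spec, rng)
    image = CalibratedImage(pixels=img, px_per_cm=spec.px_per_cm)
    if out_path is not None:
        Image.fromarray(img).save(Path(out_path), format="PNG")
    return image


# parameter ranges for product-like populations: (length cm, visible width cm)
POPULATION_DEFAULTS = {
    "carrot": {
        "kind": "tapered-carrot",
        "length_range": (14.0, 24.0),
        "width_range": (3.2, 6.4),
        "taper_range": (0.6, 0.9),
    },
    "cucumber": {
        "kind": "spindle",
        "length_range": (13.0, 21.0),
        "width_range": (2.6, 5.2),
        "exponent_range": (0.25, 0.45),
    },
}


def sample_population_shapes(
    product: ProductProfile, n: int, seed: int, overrides: dict | None = None
) -> list[ShapeSpec]:
    """Draw n deterministic product-like shapes from the default ranges."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    cfg = dict(POPULATION_DEFAULTS.get(product.name, POPULATION_DEFAULTS["carrot"]))
    if overrides:
        cfg.update(overrides)
    rng = np.random.default_rng(seed)
    shapes = []
    for _ in range(n):
        length = rng.uniform(*cfg["length_range"])
        width = rng.uniform(*cfg["width_range"])
        params = {}
        if cfg["kind"] == "tapered-carrot":
            params["taper_exponent"] = rng.uniform(*cfg["taper_range"])
        elif cfg["kind"] == "spindle":
            params["exponent"] = rng.uniform(*cfg["exponent_range"])
        shapes.append(
            make_shape(
                cfg["kind"],
                length=length,
                max_width=width,
                aspect_ratio=product.aspect_ratio,
                **params,
            )
        )
    return shapes


def make_population(
    product: ProductProfile,
    n: int,
    seed: int,
    out_dir: str | Path,
    render: RenderSpec | None = None,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Generate a dataset of n images plus ground_truth.csv and a manifest.

    Returns the ground-truth table.  Fully deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    render = render or RenderSpec()
    shapes = sample_population_shapes(product, n, seed, overrides)
    rows = []
    for i, shape in enumerate(shapes):
        img_seed = seed + 1000 + i
        rot = float(np.random.default_rng(img_seed).uniform(0.0, 180.0))
        spec_i = replace(render, rotation_deg=rot)
        fname = f"{product.name}_{i:04d}.png"
        _, truth = render_top_view(
            shape,
            spec_i,
            seed=img_seed,
            density=product.density,
            product=product,
            out_path=out_dir / fname,
        )
        rows.append(
            {
                "file": fname,
                "kind": truth.kind,
                "seed": img_seed,
                "volume_ml": truth.volume_ml,
                "mass_g": truth.mass_g,
                "class": truth.class_label,
                "length_cm": truth.length_cm,
                "max_width_cm": truth.max_width_cm,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest = {
        "product": product.name,
        "n": n,
        "seed": seed,
        "px_per_cm": render.px_per_cm,
        "aspect_ratio": product.aspect_ratio,
        "density_g_per_ml": product.density,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table
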