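"""From a calibrated top-view image to a width profile.

Pipeline: color threshold -> morphological cleanup -> largest connected
component -> minimum-area rotated bounding box -> cross-widths at equally
spaced stations along the box's length axis.

Coordinates are image row-major with the origin at the top-left pixel
corner; pixel (r, c) occupies the square [r, r+1) x [c, c+1).  All geometry
is reported in centimetres after division by the calibration factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage import color as skcolor
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "CalibratedImage",
    "Silhouette",
    "RotatedBox",
    "WidthProfile",
    "ThresholdConfig",
    "extract_silhouette",
    "min_area_box",
    "width_profile",
]

MIN_IMAGE_SIDE = 32


@dataclass(frozen=True)
class CalibratedImage:
    """An RGB raster with a pixels-per-centimetre calibration factor."""

    pixels: np.ndarray  # H x W x 3, uint8
    px_per_cm: float

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if min(p.shape[:2]) < MIN_IMAGE_SIDE:
            raise ValueError(f"image sides must be >= {MIN_IMAGE_SIDE} px")


@dataclass(frozen=True)
class Silhouette:
    """Binary foreground mask of a single object, with calibration."""

    mask: np.ndarray  # H x W, bool
    px_per_cm: float
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        if not self.mask.any():
            raise ValueError("silhouette mask is empty")

    @property
    def area_cm2(self) -> float:
        return float(self.mask.sum()) / self.px_per_cm**2


@dataclass(frozen=True)
class RotatedBox:
    """Minimum-area rotated rectangle around the silhouette.

    ``length`` is the longer side and ``width`` the shorter one, in cm.
    ``angle`` is the direction of the length axis in degrees, measured in
    image (x right, y down) coordinates and normalised to [0, 180).
    ``corner`` is the pixel-space corner from which stations are measured,
    and ``axis_u``/``axis_v`` are the unit vectors of the length and width
    directions (pixel space, (x, y) order).
    """

    center: tuple[float, float]
    length: float
    width: float
    angle: float
    px_per_cm: float
    corner: tuple[float, float] = field(repr=False, default=(0.0, 0.0))
    axis_u: tuple[float, float] = field(repr=False, default=(1.0, 0.0))
    axis_v: tuple[float, float] = field(repr=False, default=(0.0, 1.0))

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("need length >= width > 0")
        if not (0.0 <= self.angle < 180.0):
            raise ValueError("angle must lie in [0, 180)")


@dataclass(frozen=True)
class WidthProfile:
    """Cross-widths (cm) at the n+1 equally spaced slice-boundary stations."""

    n_slices: int
    stations: np.ndarray  # cm from one end face, strictly increasing
    widths: np.ndarray  # cm, same length as stations
    length: float  # cm, box length

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError("need at least 3 slices")
        if len(self.stations) != self.n_slices + 1 or len(self.widths) != len(self.stations):
            raise ValueError("stations/widths must have n_slices + 1 entries")
        if np.any(np.diff(self.stations) <= 0):
            raise ValueError("stations must be strictly increasing")
        if np.any(np.asarray(self.widths) < 0):
            raise ValueError("widths must be >= 0")

    @property
    def slice_height(self) -> float:
        return self.length / self.n_slices


@dataclass(frozen=True)
class ThresholdConfig:
    """HSV box threshold for foreground extraction.

    Defaults accept any strongly saturated hue, which separates typical
    produce colors (orange, green, red) from a white/grey background.  Set
    ``auto_otsu`` to threshold the saturation channel with Otsu's method
    instead of the fixed box.
    """

    hue_low: float = 0.0
    hue_high: float = 1.0
    sat_min: float = 0.25
    val_min: float = 0.15
    val_max: float = 1.0
    auto_otsu: bool = False


def _hsv_mask(rgb: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    hsv = skcolor.rgb2hsv(rgb)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if cfg.auto_otsu:
        sat_thresh = threshold_otsu(s)
        mask = s > sat_thresh
    else:
        if cfg.hue_low <= cfg.hue_high:
            hue_ok = (h >= cfg.hue_low) & (h <= cfg.hue_high)
        else:  # wrap-around range, e.g. red hues
            hue_ok = (h >= cfg.hue_low) | (h <= cfg.hue_high)
        mask = hue_ok & (s >= cfg.sat_min)
    return mask & (v >= cfg.val_min) & (v <= cfg.val_max)


def extract_silhouette(
    image: CalibratedImage, config: ThresholdConfig | None = None
) -> Silhouette:
    """Threshold, clean up and keep the largest connected component.

    Raises
    ------
    ValueError
        If no foreground pixel survives thresholding ("no object detected").
    """
    cfg = config or ThresholdConfig()
    mask = _hsv_mask(image.pixels, cfg)
    if not mask.any():
        raise ValueError("no object detected")
    footprint = np.ones((3, 3), dtype=bool)
    mask = morphology.opening(mask, footprint)
    mask = morphology.closing(mask, footprint)
    if not mask.any():
        raise ValueError("no object detected")
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    touches = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if touches:
        warnings.warn("foreground touches the image border", stacklevel=2)
    return Silhouette(mask=mask, px_per_cm=image.px_per_cm, touches_border=touches)


def _pixel_corner_cloud(mask: np.ndarray) -> np.ndarray:
    """Corners of the foreground pixel footprints, (x, y) order.

    Working with pixel-square corners rather than centers makes an
    axis-aligned w x h pixel block measure exactly w x h, not (w-1) x (h-1).
    Only convex-hull pixels contribute, which keeps the cloud small.
    """
    rows, cols = np.nonzero(mask)
    centers = np.column_stack([cols + 0.5, rows + 0.5]).astype(float)
    hull = MultiPoint(centers).convex_hull
    hull_pts = shapely.get_coordinates(hull)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (hull_pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def min_area_box(sil: Silhouette) -> RotatedBox:
    """Minimum-area rotated rectangle of the foreground (rotating calipers)."""
    if sil.mask.sum() < 3:
        raise ValueError("mask too small for a bounding box")
    cloud = _pixel_corner_cloud(sil.mask)
    rect = MultiPoint(cloud).minimum_rotated_rectangle
    corners = shapely.get_coordinates(rect)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    len1, len2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if len1 >= len2:
        long_px, short_px = len1, len2
        u_vec, v_vec = e1 / len1, e2 / len2
    else:
        long_px, short_px = len2, len1
        u_vec, v_vec = e2 / len2, e1 / len1
    angle = math.degrees(math.atan2(u_vec[1], u_vec[0])) % 180.0
    center = corners.mean(axis=0)
    # corner chosen so that corner + t*u + s*v spans the box for
    # t in [0, long_px], s in [0, short_px]
    corner = center - u_vec * long_px / 2.0 - v_vec * short_px / 2.0
    return RotatedBox(
        center=(float(center[0]), float(center[1])),
        length=long_px / sil.px_per_cm,
        width=short_px / sil.px_per_cm,
        angle=float(angle),
        px_per_cm=sil.px_per_cm,
        corner=(float(corner[0]), float(corner[1])),
        axis_u=(float(u_vec[0]), float(u_vec[1])),
        axis_v=(float(v_vec[0]), float(v_vec[1])),
    )


def _scanline_width_px(
    mask: np.ndarray,
    origin: np.ndarray,
    direction: np.ndarray,
    span_px: float,
    step: float,
) -> float:
    """Caliper span of foreground along one scan line, in pixels."""
    n = max(int(math.ceil(span_px / step)) + 1, 2)
    s = np.linspace(0.0, span_px, n)
    pts = origin[None, :] + s[:, None] * direction[None, :]
    cols = np.floor(pts[:, 0]).astype(int)
    rows = np.floor(pts[:, 1]).astype(int)
    h, w = mask.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    fg = np.zeros(n, dtype=bool)
    fg[inside] = mask[rows[inside], cols[inside]]
    if not fg.any():
        return 0.0
    idx = np.nonzero(fg)[0]
    span = s[idx[-1]] - s[idx[0]]
    # each foreground sample stands for a pixel footprint of one step
    return float(span + s[1] - s[0])


def width_profile(
    sil: Silhouette, box: RotatedBox, n_slices: int, step_px: float = 0.5
) -> WidthProfile:
    """Cross-widths perpendicular to the box's length axis.

    Measures the caliper span (distance between the two extreme foreground
    samples) on ``n_slices + 1`` equally spaced lines, sampled at a
    sub-pixel step of ``step_px``.
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    length_px = box.length * box.px_per_cm
    width_px = box.width * box.px_per_cm
    corner = np.asarray(box.corner)
    u = np.asarray(box.axis_u)
    v = np.asarray(box.axis_v)
    eps = min(step_px / 2.0, length_px / 1000.0)
    widths = np.empty(n_slices + 1)
    for k in range(n_slices + 1):
        t = k * length_px / n_slices
        t = min(max(t, eps), length_px - eps)  # stay inside the box faces
        origin = corner + t * u
        widths[k] = _scanline_width_px(sil.mask, origin, v, width_px, step_px)
    stations = np.linspace(0.0, box.length, n_slices + 1)
    return WidthProfile(
        n_slices=n_slices,
        stations=stations,
        widths=widths / box.px_per_cm,
        length=box.length,
    )
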