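"""Closed-form solid-geometry primitives.

All functions are pure and operate on centimetre-scale quantities; volumes
come out in cm^3 (equivalently mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrustumSpec",
    "EllipseDims",
    "ConicCoefficients",
    "EllipseFit",
    "frustum_volume",
    "ellipse_area",
    "cap_volume",
    "disk_area_two_view",
    "wdm_volume",
    "fit_ellipse",
]


@dataclass(frozen=True)
class FrustumSpec:
    """A frustum ("chopped pyramid") between two parallel cross-sections.

    Attributes
    ----------
    area_top : float
        Area of the top cross-section, cm^2.
    area_bottom : float
        Area of the bottom cross-section, cm^2.
    height : float
        Perpendicular distance between the two sections, cm.
    """

    area_top: float
    area_bottom: float
    height: float

    def __post_init__(self) -> None:
        if self.area_top < 0 or self.area_bottom < 0:
            raise ValueError("frustum cross-section areas must be >= 0")
        if self.height < 0:
            raise ValueError("frustum height must be >= 0")


@dataclass(frozen=True)
class EllipseDims:
    """Full diameters of an elliptical cross-section.

    ``d1`` is the in-plane (visible) diameter, ``d2`` the out-of-plane one.
    """

    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("ellipse diameters must be >= 0")


@dataclass(frozen=True)
class ConicCoefficients:
    """Algebraic conic a x^2 + b xy + c y^2 + d x + e y + f = 0."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @property
    def discriminant(self) -> float:
        return self.b * self.b - 4.0 * self.a * self.c

    def is_ellipse(self, tol: float = 1e-12) -> bool:
        return self.discriminant < -tol


@dataclass(frozen=True)
class EllipseFit:
    """Result of fitting an ellipse to scattered points."""

    conic: ConicCoefficients
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # radians, orientation of the major axis

    @property
    def axis_ratio(self) -> float:
        """Minor/major semi-axis ratio in [0, 1]."""
        return self.semi_minor / self.semi_major


def frustum_volume(spec: FrustumSpec) -> float:
    """Volume of a frustum from its two face areas and height.

    Uses the classical prismatoid formula
    ``V = h/3 * (B + B' + sqrt(B*B'))``, exact for any pyramid or cone
    frustum.  Degenerates to ``B*h`` when the faces are equal (prism) and to
    ``B*h/3`` when one face vanishes (cone).
    """
    b, bp, h = spec.area_top, spec.area_bottom, spec.height
    return h / 3.0 * (b + bp + math.sqrt(b * bp))


def ellipse_area(dims: EllipseDims) -> float:
    """Area of an ellipse from its two full diameters: pi*(d1/2)*(d2/2)."""
    return math.pi * (dims.d1 / 2.0) * (dims.d2 / 2.0)


def cap_volume(dims: EllipseDims, height: float) -> float:
    """Volume of an end cap with elliptical base, ``pi*d1*d2*h/6``.

    .. note::
       This is the printed cap formula of the source method.  Numerically it
       equals a semi-ellipsoid with full diameters ``d1``, ``d2`` and
       half-axis ``h`` (and is exactly twice the volume of the elliptical
       cone ``pi*d1*d2*h/12`` the accompanying text names).  The printed
       formula is implemented deliberately.
    """
    if height < 0:
        raise ValueError("cap height must be >= 0")
    return math.pi * dims.d1 * dims.d2 * height / 6.0


def disk_area_two_view(d: float, z: float) -> float:
    """Elliptical disk area ``pi*d*z/4`` from two orthogonal view widths.

    ``d`` is the side-view width and ``z`` the top-view width of one disk;
    reduces to the circle area ``pi*(z/2)^2`` when ``d == z``.
    """
    if d < 0 or z < 0:
        raise ValueError("disk widths must be >= 0")
    return math.pi * d * z / 4.0


def wdm_volume(
    m_apparatus: float,
    m_fruit: float,
    m_submerged: float,
    water_density: float = 1.0,
) -> float:
    """Water-displacement reference volume ``(M1 + M2 - M3) / rho_water``.

    Parameters are the three scale readings in grams: apparatus with water
    (M1), the fruit alone (M2), and apparatus with the fruit submerged (M3).
    Returns millilitres.
    """
    if water_density <= 0:
        raise ValueError("water density must be > 0")
    return (m_apparatus + m_fruit - m_submerged) / water_density


def _conic_geometry(coef: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Center, semi-axes and major-axis angle of an algebraic conic."""
    a, b, c, d, e, f = coef
    # matrix form: [[a, b/2], [b/2, c]], linear [d, e], constant f
    m = np.array([[a, b / 2.0], [b / 2.0, c]])
    det = np.linalg.det(m)
    if det <= 0:
        raise ValueError("conic is not an ellipse")
    center = np.linalg.solve(2.0 * m, -np.array([d, e]))
    # constant term at the center
    fc = f + 0.5 * (d * center[0] + e * center[1])
    eigval, eigvec = np.linalg.eigh(m)
    # a x'^2 + c y'^2 = -fc in principal axes
    if -fc / eigval[0] <= 0 or -fc / eigval[1] <= 0:
        raise ValueError("conic is degenerate")
    axes = np.sqrt(-fc / eigval)
    order = np.argsort(axes)[::-1]
    semi_major, semi_minor = axes[order]
    major_vec = eigvec[:, order[0]]
    angle = math.atan2(major_vec[1], major_vec[0]) % math.pi
    return (float(center[0]), float(center[1])), float(semi_major), float(semi_minor), angle


def fit_ellipse(points) -> EllipseFit:
    """Direct least-squares ellipse fit (Fitzgibbon/Halir-Flusser).

    Minimises the algebraic distance of the conic subject to the
    ellipse-specific constraint ``4ac - b^2 = 1``, which guarantees the
    returned conic is an ellipse whenever the fit succeeds.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        At least 6 non-collinear sample points.

    Returns
    -------
    EllipseFit
        Conic coefficients plus derived center, semi-axes and axis ratio.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 6:
        raise ValueError("ellipse fit needs at least 6 points")

    # center/scale for numerical conditioning
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale <= 0:
        raise ValueError("degenerate point set")
    x, y = ((pts - mean) / scale).T

    d1 = np.column_stack([x * x, x * y, y * y])  # quadratic part
    d2 = np.column_stack([x, y, np.ones_like(x)])  # linear part
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point set") from exc
    m = s1 + s2 @ t
    # constraint matrix inverse applied in closed form
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(cond > 0)[0]
    if valid.size == 0:
        raise ValueError("points do not determine an ellipse")
    a1 = np.real(eigvec[:, valid[0]])
    coef_n = np.concatenate([a1, t @ a1])

    # undo normalisation: conic in original coordinates
    a, b, c, d, e, f = coef_n
    mx, my = mean
    s = scale
    coef = np.array(
        [
            a / s**2,
            b / s**2,
            c / s**2,
            d / s - (2 * a * mx + b * my) / s**2,
            e / s - (2 * c * my + b * mx) / s**2,
            f
            + (a * mx**2 + b * mx * my + c * my**2) / s**2
            - (d * mx + e * my) / s,
        ]
    )
    coef /= np.linalg.norm(coef)
    conic = ConicCoefficients(*coef)
    if not conic.is_ellipse():
        raise ValueError("fitted conic failed the ellipse condition")
    center, semi_major, semi_minor, angle = _conic_geometry(coef)
    return EllipseFit(conic, center, semi_major, semi_minor, angle)
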