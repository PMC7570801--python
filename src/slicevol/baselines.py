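"""Comparison estimators: the 1-pixel disk method (one- and two-view) and
multiple linear regression on simple geometric features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import disk_area_two_view
from .silhouette import RotatedBox, Silhouette, min_area_box, width_profile

__all__ = [
    "DiskStack",
    "MlrModel",
    "disk_volume",
    "disk_stack_from_silhouette",
    "mlr_features",
    "fit_mlr",
    "predict_mlr",
    "MLR_WIDTH_FRACTIONS",
]

# width sampling stations for the MLR feature vector, as fractions of length
MLR_WIDTH_FRACTIONS = (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)


@dataclass(frozen=True)
class DiskStack:
    """Per-disk widths of an object sliced into thin parallel disks.

    ``top_widths`` are the widths seen from above (z_i); ``side_widths``
    the widths seen from the side (d_i).  When the side view is absent the
    cross-sections are assumed circular (d_i = z_i).
    """

    thickness: float  # cm per disk
    top_widths: np.ndarray
    side_widths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("disk thickness must be > 0")
        tw = np.asarray(self.top_widths, dtype=float)
        if np.any(tw < 0):
            raise ValueError("widths must be >= 0")
        if self.side_widths is not None:
            sw = np.asarray(self.side_widths, dtype=float)
            if len(sw) != len(tw):
                raise ValueError("top and side width lists must match in length")
            if np.any(sw < 0):
                raise ValueError("widths must be >= 0")


def disk_volume(stack: DiskStack) -> float:
    """Sum of per-disk volumes A_i * x.

    One view: A_i = pi*(z_i/2)^2 (circular assumption).  Two views:
    A_i = pi*d_i*z_i/4 (elliptical disk).
    """
    z = np.asarray(stack.top_widths, dtype=float)
    d = z if stack.side_widths is None else np.asarray(stack.side_widths, dtype=float)
    areas = np.array([disk_area_two_view(di, zi) for di, zi in zip(d, z)])
    return float(areas.sum() * stack.thickness)


def disk_stack_from_silhouette(
    sil: Silhouette,
    box: RotatedBox | None = None,
    side: Silhouette | None = None,
    side_box: RotatedBox | None = None,
) -> DiskStack:
    """Build a 1-pixel-thick disk stack from a top-view silhouette.

    With a side-view silhouette the per-disk side widths are read off at the
    same axial fractions, assuming both views share the pixel scale and the
    object's axial alignment.
    """
    if box is None:
        box = min_area_box(sil)
    length_px = box.length * box.px_per_cm
    n_disks = max(int(round(length_px)), 3)
    profile = width_profile(sil, box, n_disks)
    # disk centers sit between successive boundary stations
    top = 0.5 * (profile.widths[:-1] + profile.widths[1:])
    side_w = None
    if side is not None:
        if side_box is None:
            side_box = min_area_box(side)
        side_profile = width_profile(side, side_box, n_disks)
        side_w = 0.5 * (side_profile.widths[:-1] + side_profile.widths[1:])
    return DiskStack(
        thickness=1.0 / box.px_per_cm,  # one pixel
        top_widths=np.asarray(top),
        side_widths=side_w,
    )


@dataclass(frozen=True)
class MlrModel:
    """Ordinary-least-squares linear model volume = b0 + sum(b_i * x_i)."""

    coefficients: np.ndarray  # b0..bn
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names) + 1:
            raise ValueError("coefficient count must be feature count + 1")


def mlr_features(sil: Silhouette, box: RotatedBox | None = None) -> np.ndarray:
    """Length plus five parallel widths at fractions 1/6..5/6 of the length."""
    if box is None:
        box = min_area_box(sil)
    profile = width_profile(sil, box, 6)
    return np.concatenate([[box.length], profile.widths[1:6]])


def fit_mlr(features: np.ndarray, volumes: np.ndarray, feature_names=None) -> MlrModel:
    """Fit OLS coefficients mapping features to reference volumes."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(volumes, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D sample x feature array")
    n, p = x.shape
    if len(y) != n:
        raise ValueError("feature and volume sample counts differ")
    design = np.column_stack([np.ones(n), x])
    if n < p + 1 or np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if feature_names is None:
        feature_names = tuple(f"x{i + 1}" for i in range(p))
    return MlrModel(coefficients=coef, feature_names=tuple(feature_names))


def predict_mlr(model: MlrModel, features: np.ndarray) -> np.ndarray | float:
    """Evaluate b0 + sum(b_i * x_i) for one sample or a batch."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != len(model.feature_names):
        raise ValueError("feature count does not match the model")
    pred = model.coefficients[0] + x @ model.coefficients[1:]
    return float(pred[0]) if single else pred
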