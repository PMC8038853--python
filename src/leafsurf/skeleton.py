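"""Curve-skeleton extraction on a skeleton plane.

A skeleton is an ordered set of N points sampled from a least-squares
polynomial fitted to the cloud's projection onto a pair of leaf-frame
axes (the *skeleton plane*): the horizontal axis ``a`` carries the
sampling, the vertical axis ``b`` carries the distortion being modeled.

Planes used by the pipeline:

* bending — a=l, b=h, quadratic fit, sampling interval expanded 5%
  (heavily curled tips can extend past the data's l-extent);
* rolling — a=w, b=h, cubic fit, per strip;
* alignment — a=l, b=w, cubic fit (midline used to re-align strips).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    StripTooSparseError,
)
from .pointcloud_io import LEAF, PointCloud3

__all__ = [
    "SkeletonPlane",
    "Skeleton",
    "BENDING_PLANE",
    "ROLLING_PLANE",
    "ALIGNMENT_PLANE",
    "fit_skeleton_function",
    "extract_skeleton",
]

_AXIS_COLUMNS = {"l": 0, "w": 1, "h": 2}


@dataclass(frozen=True)
class SkeletonPlane:
    """A named pair of leaf-frame axes: horizontal ``a``, vertical ``b``."""

    a_axis: str
    b_axis: str

    def __post_init__(self) -> None:
        if self.a_axis not in _AXIS_COLUMNS or self.b_axis not in _AXIS_COLUMNS:
            raise ValueError("skeleton plane axes must be drawn from {l, w, h}")
        if self.a_axis == self.b_axis:
            raise ValueError("skeleton plane axes must differ")

    @property
    def a_col(self) -> int:
        return _AXIS_COLUMNS[self.a_axis]

    @property
    def b_col(self) -> int:
        return _AXIS_COLUMNS[self.b_axis]

    @property
    def extra_col(self) -> int:
        """Column of the leaf-frame axis not in the plane (restored later)."""
        return 3 - self.a_col - self.b_col


BENDING_PLANE = SkeletonPlane("l", "h")
ROLLING_PLANE = SkeletonPlane("w", "h")
ALIGNMENT_PLANE = SkeletonPlane("l", "w")


@dataclass
class Skeleton:
    """N ordered points (a_i, f(a_i)) on a skeleton plane.

    ``coeffs`` are polynomial coefficients in ascending order
    (numpy.polynomial convention). Skeletons produced by
    :func:`extract_skeleton` have strictly increasing a-coordinates and
    satisfy b = f(a) exactly; hand-built polylines (e.g. for the
    flattening operator) may be arbitrary.
    """

    points: np.ndarray          # (N, 2)
    coeffs: np.ndarray
    plane: SkeletonPlane
    sample_range: tuple         # (a_min, a_max) after any expansion

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.points) < 2:
            raise ValueError("a skeleton needs at least 2 points")

    def __len__(self) -> int:
        return len(self.points)

    def to_json(self) -> str:
        return json.dumps(
            {
                "plane": [self.plane.a_axis, self.plane.b_axis],
                "coeffs": np.asarray(self.coeffs).tolist(),
                "sample_range": list(self.sample_range),
                "points": self.points.tolist(),
            }
        )


def fit_skeleton_function(points2d: np.ndarray, degree: int) -> np.ndarray:
    """Ordinary least-squares polynomial b = f(a) of the given degree.

    Coefficients are returned in ascending order. Solved through the
    numerically orthogonalizing least-squares path (SVD); no
    regularization is applied.
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    if len(pts) < degree + 1:
        raise InsufficientPointsError(
            f"{len(pts)} points cannot determine a degree-{degree} polynomial"
        )
    a, b = pts[:, 0], pts[:, 1]
    if np.ptp(a) <= 0:
        raise DegenerateGeometryError(
            "all points share one a-coordinate; no polynomial in a exists"
        )
    return npoly.polyfit(a, b, degree)


def extract_skeleton(
    cloud: PointCloud3,
    plane: SkeletonPlane,
    n_points: int = 50,
    degree: int = 2,
    expand_frac: float = 0.0,
    delta: int = 5,
) -> Skeleton:
    """Fit and sample a skeleton from a leaf-frame cloud.

    The cloud is projected onto ``plane``, a degree-``degree`` polynomial
    is fitted, the sampling interval [a_min, a_max] is widened by
    ``expand_frac`` of its width (split evenly between the two ends) and
    ``n_points`` uniformly spaced a-values are evaluated through the fit.

    Clouds with fewer than ``delta`` points raise
    :class:`StripTooSparseError` — the skip signal that drops a strip
    whose fit would be unreliable.
    """
    if cloud.frame != LEAF:
        raise ValueError("skeleton extraction expects a leaf-frame cloud")
    if len(cloud) < delta:
        raise StripTooSparseError(
            f"{len(cloud)} points < delta={delta}; strip skipped"
        )
    if n_points < 2:
        raise ValueError("need at least 2 skeleton points")
    pts = cloud.coords[:, [plane.a_col, plane.b_col]]
    coeffs = fit_skeleton_function(pts, degree)
    a_min, a_max = pts[:, 0].min(), pts[:, 0].max()
    pad = expand_frac * (a_max - a_min) / 2.0
    a_min, a_max = a_min - pad, a_max + pad
    u = np.linspace(a_min, a_max, n_points)
    s = np.stack([u, npoly.polyval(u, coeffs)], axis=1)
    return Skeleton(s, coeffs, plane, (float(a_min), float(a_max)))
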