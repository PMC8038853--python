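"""Leaf coordinate-system determination.

A leaf is described in an orthonormal frame (l, w, h):

* ``l`` — along the primary vein, base to apex, from the first principal
  component of the cloud, sign-fixed so it agrees with the centroid
  direction seen from the plant's emergence point (the world origin);
* ``h`` — the leaf-surface normal. The *smallest* principal component is
  unreliable for strongly bent leaves (bending inflates variance along
  the normal), so ``h`` is found by sweeping a candidate axis around
  ``l`` in 1° steps and minimizing the occupied-pixel count of the
  point cloud projected onto the candidate side-view plane;
* ``w = l × h`` completes the right-handed frame.

The frame's origin is the cloud centroid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .pointcloud_io import LEAF, PointCloud3

__all__ = [
    "LeafAxes",
    "ProjectionImage",
    "principal_components",
    "determine_l_axis",
    "projected_area",
    "side_view_area_profile",
    "determine_h_axis",
    "compose_axes",
    "to_leaf_frame",
    "from_leaf_frame",
    "determine_axes",
]

#: column layout of leaf-frame clouds
AXIS_COLUMNS = {"l": 0, "w": 1, "h": 2}


@dataclass
class LeafAxes:
    """The (l, w, h) leaf frame: three unit vectors plus the centroid origin."""

    l: np.ndarray
    w: np.ndarray
    h: np.ndarray
    centroid: np.ndarray
    theta_opt: float = 0.0

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=np.float64).reshape(3)
        self.w = np.asarray(self.w, dtype=np.float64).reshape(3)
        self.h = np.asarray(self.h, dtype=np.float64).reshape(3)
        self.centroid = np.asarray(self.centroid, dtype=np.float64).reshape(3)
        for v, name in ((self.l, "l"), (self.w, "w"), (self.h, "h")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"axis {name} is not unit length")
        if max(abs(self.l @ self.w), abs(self.l @ self.h), abs(self.w @ self.h)) > 1e-9:
            raise ValueError("leaf axes are not pairwise orthogonal")
        if self.h[2] < -1e-12:
            raise ValueError("h-axis must not point below the horizon (world z < 0)")

    @property
    def rotation(self) -> np.ndarray:
        """Rows l, w, h: maps world offsets into leaf coordinates."""
        return np.stack([self.l, self.w, self.h])

    def to_json(self) -> str:
        return json.dumps(
            {
                "l": self.l.tolist(),
                "w": self.w.tolist(),
                "h": self.h.tolist(),
                "centroid": self.centroid.tolist(),
                "theta_opt": self.theta_opt,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LeafAxes":
        d = json.loads(text)
        return cls(d["l"], d["w"], d["h"], d["centroid"], d.get("theta_opt", 0.0))


@dataclass
class ProjectionImage:
    """Binary occupancy image of a projected cloud on an m x m grid."""

    pixels: np.ndarray        # (m, m) bool
    extent: tuple             # ((a_lo, a_hi), (b_lo, b_hi)) in mm
    area_count: int

    def __post_init__(self) -> None:
        assert self.area_count == int(self.pixels.sum())


def principal_components(cloud: PointCloud3):
    """Eigenpairs of the 3x3 covariance of the centered cloud, descending.

    Eigenvector signs are normalized (largest-magnitude component made
    positive) to remove solver-dependent ambiguity before any
    orientation logic is applied.
    """
    if len(cloud) < 3:
        raise DegenerateGeometryError("need at least 3 points for principal axes")
    centered = cloud.coords - cloud.centroid
    cov = centered.T @ centered / (len(cloud) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[1] <= max(eigvals[0] * 1e-12, 0.0):
        raise DegenerateGeometryError("points are (nearly) collinear")
    pairs = []
    for i in range(3):
        v = eigvecs[:, i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        pairs.append((float(eigvals[i]), v))
    return pairs


def determine_l_axis(cloud: PointCloud3) -> np.ndarray:
    """Unit vein direction from base to apex.

    The first principal component is flipped, if needed, so that the
    angle between it and the centroid vector (seen from the plant's
    emergence point, the world origin) is at most 90°.
    """
    c = cloud.centroid
    norm_c = np.linalg.norm(c)
    if norm_c < 1e-12:
        raise DegenerateGeometryError(
            "centroid coincides with the origin; base-to-apex orientation undetermined"
        )
    (lam1, pc1), (lam2, _), _ = principal_components(cloud)
    if lam2 > 0 and lam1 / lam2 < 1.2:
        warnings.warn(
            "leaf length barely exceeds width (eigenvalue ratio < 1.2); "
            "vein direction may be unreliable",
            stacklevel=2,
        )
    return pc1 if c @ pc1 >= 0.0 else -pc1


def projected_area(
    cloud: PointCloud3,
    l: np.ndarray,
    h_theta: np.ndarray,
    m: int = 100,
    extent: tuple | None = None,
) -> ProjectionImage:
    """Occupancy image of the cloud projected onto the (h_theta, l) plane.

    Each point maps to the pixel containing (p . h_theta, p . l); a pixel
    is 1 if any point falls in it and the area count is the number of
    1-pixels. ``extent`` is ((h_lo, h_hi), (l_lo, l_hi)); by default it
    is taken from this single projection.
    """
    l = np.asarray(l, float)
    h_theta = np.asarray(h_theta, float)
    if abs(l @ h_theta) > 1e-10:
        raise ValueError("h_theta must be perpendicular to l")
    a = cloud.coords @ h_theta
    b = cloud.coords @ l
    if extent is None:
        extent = ((a.min(), a.max()), (b.min(), b.max()))
    (a_lo, a_hi), (b_lo, b_hi) = extent
    if a_hi <= a_lo or b_hi <= b_lo:
        raise ValueError("projection grid extent has zero width")
    ia = np.clip(((a - a_lo) / (a_hi - a_lo) * m).astype(int), 0, m - 1)
    ib = np.clip(((b - b_lo) / (b_hi - b_lo) * m).astype(int), 0, m - 1)
    pixels = np.zeros((m, m), dtype=bool)
    pixels[ia, ib] = True
    return ProjectionImage(pixels, extent, int(pixels.sum()))


def _seed_axis(l: np.ndarray) -> np.ndarray:
    """Deterministic perpendicular seed: l x (world basis vector least
    aligned with l). Any perpendicular seed is valid because the full
    half-turn is searched."""
    e_min = np.zeros(3)
    e_min[np.argmin(np.abs(l))] = 1.0
    d = np.cross(l, e_min)
    return d / np.linalg.norm(d)


def side_view_area_profile(
    cloud: PointCloud3,
    l: np.ndarray,
    m: int = 100,
    theta_step_deg: float = 1.0,
):
    """Projected occupied-cell count S(theta) for theta = 0..180 degrees.

    The cloud is centered on its centroid. The grid is sized once: along
    l from the data's l-extent, along the rotating axis symmetrically by
    the maximum radial distance of any point from the l-axis, so every
    rotated projection stays in-bounds.

    Returns ``(thetas_deg, counts, d, e)`` where the candidate axis is
    ``h_theta = d cos(theta) + e sin(theta)`` with ``e = l x d``.
    """
    if len(cloud) < 3:
        raise DegenerateGeometryError("need at least 3 points for the h-axis search")
    l = np.asarray(l, float)
    p = cloud.coords - cloud.centroid
    d = _seed_axis(l)
    e = np.cross(l, d)
    ad, ae, al = p @ d, p @ e, p @ l
    radial = np.sqrt(np.maximum(ad**2 + ae**2, 0.0))
    r = radial.max()
    if r <= 0 or al.max() <= al.min():
        raise DegenerateGeometryError("degenerate cloud for projection grid")
    b_lo, b_hi = al.min(), al.max()
    ib = np.clip(((al - b_lo) / (b_hi - b_lo) * m).astype(int), 0, m - 1)

    thetas = np.arange(0.0, 180.0 + 1e-9, theta_step_deg)
    counts = np.empty(len(thetas), dtype=int)
    for i, theta in enumerate(np.deg2rad(thetas)):
        a = ad * np.cos(theta) + ae * np.sin(theta)
        ia = np.clip(((a + r) / (2 * r) * m).astype(int), 0, m - 1)
        counts[i] = len(np.unique(ia * m + ib))
    return thetas, counts, d, e


def determine_h_axis(
    cloud: PointCloud3,
    l: np.ndarray,
    m: int = 100,
    theta_step_deg: float = 1.0,
):
    """Leaf-surface normal via the minimal side-view projected area.

    Sweeps a perpendicular axis around ``l`` over half a turn, scores
    each angle by the occupied-pixel count of the side-view projection,
    and returns the axis of the smallest count (smallest angle wins
    ties), flipped upward if its world-z component is negative.

    Returns ``(h, theta_opt_deg)``.
    """
    thetas, counts, d, e = side_view_area_profile(cloud, l, m, theta_step_deg)
    if counts.min() == counts.max():
        warnings.warn(
            "projected area is constant over all rotations (isotropic "
            "geometry); h-axis defaults to theta=0",
            stacklevel=2,
        )
    i_best = int(np.argmin(counts))
    theta_opt = float(thetas[i_best])
    t = np.deg2rad(theta_opt)
    h = d * np.cos(t) + e * np.sin(t)
    if h[2] < 0:
        h = -h
    return h / np.linalg.norm(h), theta_opt


def compose_axes(
    l: np.ndarray,
    h: np.ndarray,
    centroid: np.ndarray,
    theta_opt: float = 0.0,
) -> LeafAxes:
    """Complete the right-handed frame with w = l x h."""
    l = np.asarray(l, float)
    h = np.asarray(h, float)
    if abs(l @ h) > 1e-10:
        raise ValueError("l and h must be perpendicular")
    w = np.cross(l, h)
    return LeafAxes(l, w / np.linalg.norm(w), h, centroid, theta_opt)


def to_leaf_frame(cloud: PointCloud3, axes: LeafAxes) -> PointCloud3:
    """Map each point p to ((p-c).l, (p-c).w, (p-c).h), frame='leaf'."""
    coords = (cloud.coords - axes.centroid) @ axes.rotation.T
    return cloud.with_coords(coords, frame=LEAF)


def from_leaf_frame(cloud: PointCloud3, axes: LeafAxes) -> PointCloud3:
    """Inverse of :func:`to_leaf_frame`."""
    coords = cloud.coords @ axes.rotation + axes.centroid
    return cloud.with_coords(coords, frame="world")


def determine_axes(
    cloud: PointCloud3, m: int = 100, theta_step_deg: float = 1.0
) -> LeafAxes:
    """Full leaf-frame determination: l from PCA + emergence-point
    orientation, h from the minimal side-view area sweep, w = l x h."""
    l = determine_l_axis(cloud)
    h, theta_opt = determine_h_axis(cloud, l, m=m, theta_step_deg=theta_step_deg)
    return compose_axes(l, h, cloud.centroid, theta_opt)
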