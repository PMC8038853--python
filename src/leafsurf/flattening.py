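"""Piecewise skeleton flattening: the heart of the reconstruction.

The skeleton polyline is unrolled segment by segment onto its plane's
a-axis; every cloud point is carried along by the rigid rotation of the
segment whose flattened interval captures it. Because each segment map
is an isometry, chord lengths — and hence strip areas — are conserved.

The full method applies this operator twice:

1. *bending* — skeleton on the lh-plane (quadratic, 5% expanded
   sampling) straightens the primary-vein curvature and partitions the
   cloud into N-1 strips along l;
2. *rolling* — each strip gets its own wh-plane skeleton (cubic) and is
   unrolled across the leaf; strips are then re-aligned to the leaf's
   wl midline through landmark points so the union is continuous.

Projecting the result onto the wl-plane yields the flattened 2D shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSegmentError, PipelineError
from .pointcloud_io import LEAF, PointCloud3
from .skeleton import (
    ALIGNMENT_PLANE,
    BENDING_PLANE,
    ROLLING_PLANE,
    Skeleton,
    extract_skeleton,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FlattenedSkeleton",
    "StripSet",
    "LeafSurface2D",
    "segment_angle",
    "flatten_skeleton",
    "flatten_bending",
    "compute_alignment_skeleton",
    "find_landmark",
    "flatten_rolling",
    "acquire_shape",
    "BendingResult",
    "RollingResult",
]


@dataclass
class FlattenedSkeleton:
    """Skeleton unrolled onto the a-axis.

    ``points[k]`` is s'_k (b-component numerically zero), ``offsets[k]``
    the cumulative translation t_k applied at segment k and
    ``angles[k]`` the rotation of segment k in radians.
    """

    points: np.ndarray      # (N, 2)
    offsets: np.ndarray     # (N-1,)
    angles: np.ndarray      # (N-1,)
    plane: object = None

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


@dataclass
class StripSet:
    """Partition of a flattened cloud into per-segment strips.

    ``strips[k]`` is the 3D leaf-frame cloud of points harvested in the
    flattened interval [s'_k, s'_{k+1}) (last interval closed); a strip
    with no points is an empty cloud. Points never captured by any
    interval are recorded as dropped.
    """

    strips: list            # list[PointCloud3]
    boundaries: np.ndarray  # (N-1, 2) flattened a-intervals
    dropped: np.ndarray     # identity labels of uncaptured points
    total_input: int = 0

    @property
    def dropped_count(self) -> int:
        return len(self.dropped)

    def union(self, frame: str = LEAF) -> PointCloud3:
        parts = [s for s in self.strips if len(s)]
        if not parts:
            raise PipelineError("strip set is empty; no points survived flattening")
        return PointCloud3(
            np.concatenate([s.coords for s in parts]),
            frame=frame,
            index=np.concatenate([s.index for s in parts]),
        )


@dataclass
class LeafSurface2D:
    """The final flattened leaf shape: 2D (l, w) points plus skeletons."""

    points: np.ndarray                       # (M', 2) columns (l, w), mm
    bending_skeleton: FlattenedSkeleton
    strip_skeletons: list = field(default_factory=list)


def segment_angle(s_k: np.ndarray, s_k1: np.ndarray) -> float:
    """Rotation (radians, (-pi, pi]) that lands segment s_k -> s_k1 on the
    positive a-axis: phi = atan2(-delta_b, delta_a)."""
    d = np.asarray(s_k1, float) - np.asarray(s_k, float)
    n = math.hypot(d[0], d[1])
    if n == 0.0:
        raise DegenerateSegmentError("coincident skeleton points define no segment")
    phi = math.atan2(-d[1], d[0])
    if phi == -math.pi:     # straight-back segment: normalize -pi to +pi
        phi = math.pi
    return phi


def _rot(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


def flatten_skeleton(
    skeleton: Skeleton, cloud: PointCloud3
) -> tuple[FlattenedSkeleton, StripSet]:
    """Unroll a skeleton onto its a-axis and carry the cloud with it.

    Iterating over segments k = 0..N-2: the segment is rotated by
    phi_k about s_k onto the a-axis and translated by the cumulative
    flattened length t_k; every not-yet-assigned cloud point receives
    the same rigid map, and those whose flattened a-coordinate falls in
    [s'_k, s'_{k+1}) (last interval closed at the right) are harvested
    into strip k. The plane's unused third coordinate is re-attached so
    strips are full 3D leaf-frame clouds.

    Points landing before the first or after the last flattened
    skeleton point under every segment map are dropped (and counted);
    the bending stage mitigates this with its 5% sampling expansion.
    """
    if len(skeleton) < 2:
        raise ValueError("skeleton must have at least 2 points")
    if cloud.frame != LEAF:
        raise ValueError("flattening expects a leaf-frame cloud")
    plane = skeleton.plane
    s = skeleton.points
    n = len(s)
    q = cloud.coords[:, [plane.a_col, plane.b_col]]
    extras = cloud.coords[:, plane.extra_col]

    flat = np.zeros((n, 2))
    offsets = np.zeros(n - 1)
    angles = np.zeros(n - 1)
    strips: list[PointCloud3] = []
    boundaries = np.zeros((n - 1, 2))

    remaining = np.arange(len(q))
    t_k = 0.0
    for k in range(n - 1):
        phi = segment_angle(s[k], s[k + 1])
        angles[k] = phi
        offsets[k] = t_k
        rot = _rot(phi)
        flat[k + 1] = rot @ (s[k + 1] - s[k]) + np.array([t_k, 0.0])

        v = (q[remaining] - s[k]) @ rot.T
        v[:, 0] += t_k
        lo, hi = flat[k, 0], flat[k + 1, 0]
        boundaries[k] = (lo, hi)
        if k < n - 2:
            mask = (v[:, 0] >= lo) & (v[:, 0] < hi)
        else:
            mask = (v[:, 0] >= lo) & (v[:, 0] <= hi)

        coords3 = np.zeros((int(mask.sum()), 3))
        coords3[:, plane.a_col] = v[mask, 0]
        coords3[:, plane.b_col] = v[mask, 1]
        coords3[:, plane.extra_col] = extras[remaining[mask]]
        strips.append(
            PointCloud3(coords3, frame=LEAF, index=cloud.index[remaining[mask]])
        )
        remaining = remaining[~mask]
        t_k = flat[k + 1, 0]

    dropped = cloud.index[remaining]
    if len(dropped):
        logger.debug(
            "flatten_skeleton(%s%s): %d point(s) fell outside every strip interval",
            plane.a_axis, plane.b_axis, len(dropped),
        )
    return (
        FlattenedSkeleton(flat, offsets, angles, plane),
        StripSet(strips, boundaries, dropped, total_input=len(cloud)),
    )


# ---------------------------------------------------------------------------
# Bending direction
# ---------------------------------------------------------------------------

@dataclass
class BendingResult:
    flattened: PointCloud3            # P' — cloud flattened along the vein
    strips: StripSet                  # strips reused by the rolling stage
    skeleton: FlattenedSkeleton       # S'_lh — drives the area computation
    raw_skeleton: Skeleton


def flatten_bending(
    cloud: PointCloud3,
    n_points: int = 50,
    degree: int = 2,
    expand_frac: float = 0.05,
    delta: int = 5,
) -> BendingResult:
    """Remove primary-vein (bending) distortion.

    The lh-plane skeleton (quadratic fit, sampling interval expanded by
    ``expand_frac``) is unrolled onto the l-axis; the returned strips
    are the input for the rolling stage.
    """
    skel = extract_skeleton(
        cloud, BENDING_PLANE, n_points=n_points, degree=degree,
        expand_frac=expand_frac, delta=delta,
    )
    flat_skel, strips = flatten_skeleton(skel, cloud)
    return BendingResult(strips.union(), strips, flat_skel, skel)


# ---------------------------------------------------------------------------
# Rolling direction
# ---------------------------------------------------------------------------

def compute_alignment_skeleton(
    cloud: PointCloud3, n_points: int = 50, degree: int = 3, delta: int = 5
) -> Skeleton:
    """Midline skeleton on the wl-plane (a=l, b=w) of the whole leaf.

    Its k-th point is the alignment anchor for strip k when the rolled
    strips are re-assembled.
    """
    return extract_skeleton(
        cloud, ALIGNMENT_PLANE, n_points=n_points, degree=degree, delta=delta
    )


def find_landmark(
    strip_skeleton: Skeleton,
    alignment_point: np.ndarray,
    strip_l_range: tuple,
) -> int:
    """Index of the strip-skeleton point nearest the alignment anchor.

    Both points are lifted to 3D before measuring distance: the strip
    skeleton point (w_i, h_i) receives l = the midpoint of the strip's
    flattened l-interval; the alignment point (l_k, w_k) receives h = 0.
    Ties break to the lower index.
    """
    pts = strip_skeleton.points          # (w_i, h_i)
    l_k, w_k = float(alignment_point[0]), float(alignment_point[1])
    l_mid = 0.5 * (strip_l_range[0] + strip_l_range[1])
    d2 = (pts[:, 0] - w_k) ** 2 + pts[:, 1] ** 2 + (l_mid - l_k) ** 2
    return int(np.argmin(d2))


@dataclass
class RollingResult:
    flattened: PointCloud3                # P'' — flattened in both directions
    strips: list                          # aligned P'^(k); None where skipped
    strip_skeletons: list                 # FlattenedSkeleton or None per strip
    alignment_skeleton: Skeleton
    skipped: list                         # indices of strips skipped (< delta)
    dropped_count: int = 0                # points lost inside strip flattening


def flatten_rolling(
    strips: StripSet,
    cloud: PointCloud3,
    n_points: int = 50,
    degree: int = 3,
    alignment_degree: int = 3,
    delta: int = 5,
) -> RollingResult:
    """Remove secondary-vein (rolling) distortion strip by strip.

    Every strip from the bending stage gets a wh-plane cubic skeleton
    and is unrolled onto the w-axis. Because each unrolled strip starts
    at its own origin, strips are re-aligned: the strip-skeleton point
    closest (in 3D) to the k-th point of the leaf's wl midline skeleton
    is the landmark, and the strip is translated so that the landmark's
    flattened position becomes the strip origin. Strips with fewer than
    ``delta`` points are skipped and logged (a gap remains — no
    interpolation is attempted).

    ``cloud`` is the pre-bending leaf-frame cloud; only the wl midline
    is computed from it.
    """
    align = compute_alignment_skeleton(
        cloud, n_points=n_points, degree=alignment_degree, delta=delta
    )
    out_strips: list = []
    out_skels: list = []
    skipped: list[int] = []
    dropped = 0
    for k, strip in enumerate(strips.strips):
        if len(strip) < delta:
            skipped.append(k)
            out_strips.append(None)
            out_skels.append(None)
            logger.info("strip %d skipped: %d point(s) < delta=%d", k, len(strip), delta)
            continue
        skel_k = extract_skeleton(
            strip, ROLLING_PLANE, n_points=n_points, degree=degree, delta=delta
        )
        flat_skel_k, sub = flatten_skeleton(skel_k, strip)
        dropped += sub.dropped_count
        rolled = sub.union()
        cl = find_landmark(skel_k, align.points[k], tuple(strips.boundaries[k]))
        landmark = flat_skel_k.points[cl]        # (w', b'~0) on the wh-plane; l = 0
        shift = np.zeros(3)
        shift[ROLLING_PLANE.a_col] = landmark[0]
        shift[ROLLING_PLANE.b_col] = landmark[1]
        aligned = rolled.with_coords(rolled.coords - shift)
        shifted_skel = FlattenedSkeleton(
            flat_skel_k.points - landmark,
            flat_skel_k.offsets,
            flat_skel_k.angles,
            flat_skel_k.plane,
        )
        out_strips.append(aligned)
        out_skels.append(shifted_skel)

    kept = [s for s in out_strips if s is not None and len(s)]
    if not kept:
        raise PipelineError("every strip was skipped; rolling stage produced no points")
    flattened = PointCloud3(
        np.concatenate([s.coords for s in kept]),
        frame=LEAF,
        index=np.concatenate([s.index for s in kept]),
    )
    return RollingResult(flattened, out_strips, out_skels, align, skipped, dropped)


# ---------------------------------------------------------------------------
# Shape acquisition
# ---------------------------------------------------------------------------

def acquire_shape(
    flattened: PointCloud3,
    bending_skeleton: FlattenedSkeleton,
    strip_skeletons: list | None = None,
) -> LeafSurface2D:
    """Project the doubly flattened cloud onto the wl-plane (drop h)."""
    pts = flattened.coords[:, [0, 1]]        # (l, w)
    return LeafSurface2D(pts, bending_skeleton, strip_skeletons or [])
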