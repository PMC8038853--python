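"""Ground-truthed synthetic leaf point clouds.

The generator builds a flat ovate leaf on the wl-plane and distorts it
with the *exact inverse* of the piecewise skeleton-flattening operator:
the straight bending skeleton is bent onto a quadratic curve segment by
segment (each segment a rigid rotation + translation), and each strip's
cross-section is rolled onto a cubic curve the same way. Because every
step is a piecewise isometry, the distorted leaf's flattenable area
equals the flat leaf's analytic area by construction — which is what
makes round-trip tests of the reconstruction falsifiable. Naive
h-displacement would stretch the surface and leave "true flat area"
undefined.

Gaussian sensor noise, spherical missing-point holes and an arbitrary
rigid pose emulate what a laser light-section scanner delivers.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .axes import LeafAxes, compose_axes, to_leaf_frame
from .errors import GenerationError
from .pointcloud_io import LEAF, WORLD, PointCloud3

__all__ = [
    "SyntheticLeafSpec",
    "SyntheticLeaf",
    "bend_coeffs_from_sag",
    "roll_coeffs_from_amplitude",
    "make_flat_leaf",
    "apply_inverse_flattening",
    "add_noise",
    "punch_holes",
    "random_rigid_pose",
    "generate_leaf",
    "generate_time_series",
    "preset",
]


def bend_coeffs_from_sag(sag: float, length: float) -> tuple:
    """Quadratic vein curve h = 4*sag*l*(L-l)/L^2: zero at base and apex,
    maximum deflection ``sag`` at mid-leaf. Ascending coefficients."""
    return (0.0, 4.0 * sag / length, -4.0 * sag / length**2)


def roll_coeffs_from_amplitude(amplitude: float, max_width: float) -> tuple:
    """Cubic cross-section curve with edge deflection ~``amplitude``.

    A 60/40 mix of even (both edges curl the same way) and odd (one edge
    curls more) terms, the asymmetry real leaves show. Ascending
    coefficients in w.
    """
    half = max_width / 2.0
    return (0.0, 0.0, 0.6 * amplitude / half**2, 0.4 * amplitude / half**3)


@dataclass
class SyntheticLeafSpec:
    """Full parameterization of one synthetic leaf.

    The outline half-width profile is
    ``w_half(l) = (W/2) * sin(pi * l / L) ** p``; the analytic flat area
    is its integral (available as :attr:`true_area`). ``bend_sag`` and
    ``roll_amplitude`` are peak deflections in mm; explicit coefficient
    tuples override them.
    """

    length: float = 100.0            # L, mm
    max_width: float = 40.0          # W, mm
    outline_exponent: float = 1.0    # p
    density: float = 2.0             # points per mm^2
    bend_sag: float = 15.0           # mm
    roll_amplitude: float = 5.0      # mm
    bend_coeffs: tuple | None = None
    roll_coeffs: tuple | None = None
    noise_sigma: float = 0.0         # mm, isotropic
    n_holes: int = 0
    hole_radius: float = 0.0         # mm
    apply_pose: bool = False
    seed: int = 0
    n_segments: int = 49             # strips used by the inverse operator

    def __post_init__(self) -> None:
        if self.length <= 0 or self.max_width <= 0 or self.density <= 0:
            raise ValueError("length, max_width and density must be positive")

    def resolved_bend_coeffs(self) -> tuple:
        if self.bend_coeffs is not None:
            return tuple(self.bend_coeffs)
        return bend_coeffs_from_sag(self.bend_sag, self.length)

    def resolved_roll_coeffs(self) -> tuple:
        if self.roll_coeffs is not None:
            return tuple(self.roll_coeffs)
        return roll_coeffs_from_amplitude(self.roll_amplitude, self.max_width)

    def half_width(self, l: np.ndarray) -> np.ndarray:
        frac = np.clip(np.asarray(l, float) / self.length, 0.0, 1.0)
        return (self.max_width / 2.0) * np.sin(np.pi * frac) ** self.outline_exponent

    @property
    def true_area(self) -> float:
        """Analytic flat area, mm^2 (numeric quadrature of the outline)."""
        integral, _ = quad(
            lambda u: np.sin(np.pi * u) ** self.outline_exponent, 0.0, 1.0
        )
        return self.max_width * self.length * integral

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticLeafSpec":
        d = json.loads(text)
        for key in ("bend_coeffs", "roll_coeffs"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def preset(name: str, **overrides) -> SyntheticLeafSpec:
    """Species-flavored parameter sets.

    ``sugarbeet`` — large, strongly bent and rolled leaf (the species
    with the most distortion); ``soybean`` — smaller leaf with milder
    distortion. Both carry mild sensor noise and a couple of small
    occlusion holes by default.
    """
    if name == "sugarbeet":
        spec = SyntheticLeafSpec(
            length=120.0, max_width=50.0, outline_exponent=1.2, density=2.0,
            bend_sag=30.0, roll_amplitude=9.0, noise_sigma=0.3,
            n_holes=2, hole_radius=4.0,
        )
    elif name == "soybean":
        spec = SyntheticLeafSpec(
            length=70.0, max_width=45.0, outline_exponent=1.0, density=2.0,
            bend_sag=8.0, roll_amplitude=3.0, noise_sigma=0.3,
            n_holes=1, hole_radius=3.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return dataclasses.replace(spec, **overrides)


# ---------------------------------------------------------------------------
# Flat leaf sampling
# ---------------------------------------------------------------------------

def make_flat_leaf(
    spec: SyntheticLeafSpec, rng: np.random.Generator | None = None
) -> tuple[PointCloud3, float]:
    """Quasi-uniform sampling of the flat outline's interior (h = 0).

    Uniform candidates in the bounding box are thinned by the outline,
    so the retained count is Binomial with mean density * true_area.
    Coordinates are leaf-frame-like columns (l, w, h) with the base at
    l = 0.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n_box = int(round(spec.density * spec.length * spec.max_width))
    l = rng.uniform(0.0, spec.length, n_box)
    w = rng.uniform(-spec.max_width / 2.0, spec.max_width / 2.0, n_box)
    keep = np.abs(w) <= spec.half_width(l)
    coords = np.stack([l[keep], w[keep], np.zeros(int(keep.sum()))], axis=1)
    area = spec.true_area
    if keep.sum() < 5 * spec.n_segments:
        warnings.warn(
            "density too low to guarantee >= 5 points per prospective strip",
            stacklevel=2,
        )
    return PointCloud3(coords, frame=LEAF), area


# ---------------------------------------------------------------------------
# Inverse flattening (the distortion operator)
# ---------------------------------------------------------------------------

def _chord_step(g, a_k: float, b_k: float, seg_len: float, direction: int) -> float:
    """Next a-value along b = g(a) whose chord from (a_k, b_k) has length
    ``seg_len``; ``direction`` is +1 (forward) or -1 (backward)."""
    def chord(a):
        return np.hypot(a - a_k, g(a) - b_k) - seg_len

    hi = a_k + direction * seg_len      # |chord| >= |da|, so the root is inside
    if chord(hi) < 0:                   # numerically flat curve
        return hi
    try:
        lo, hi = (a_k, hi) if direction > 0 else (hi, a_k)
        a_next = brentq(chord, lo, hi, xtol=1e-12)
    except ValueError as exc:           # pragma: no cover - defensive
        raise GenerationError(f"distortion curve step insoluble: {exc}") from exc
    if direction * (a_next - a_k) <= 0:
        raise GenerationError("distortion curve too extreme; strips self-intersect")
    return a_next


def _curve_nodes(
    coeffs, a_start: float, seg_len: float, n_seg: int, anchor: float | None = None
) -> np.ndarray:
    """Points on the curve b = g(a) whose consecutive chords all have
    length ``seg_len``. Returns (n_seg+1, 2).

    With ``anchor=None`` the chain starts at a = a_start and steps
    forward. With an anchor (the sag apex for the bending quadratic,
    w = 0 for the roll cubic) the chain is built outward from it in
    both directions, so a symmetric curve yields a symmetric distorted
    leaf whose mean orientation matches the declared true axes.
    """
    def g(a):
        return npoly.polyval(a, coeffs)

    nodes = np.zeros((n_seg + 1, 2))
    if anchor is None:
        nodes[0] = (a_start, g(a_start))
        for k in range(n_seg):
            a_next = _chord_step(g, nodes[k, 0], nodes[k, 1], seg_len, +1)
            nodes[k + 1] = (a_next, g(a_next))
    else:
        mid = (n_seg + 1) // 2
        nodes[mid] = (anchor, g(anchor))
        for k in range(mid, n_seg):
            a_next = _chord_step(g, nodes[k, 0], nodes[k, 1], seg_len, +1)
            nodes[k + 1] = (a_next, g(a_next))
        for k in range(mid, 0, -1):
            a_prev = _chord_step(g, nodes[k, 0], nodes[k, 1], seg_len, -1)
            nodes[k - 1] = (a_prev, g(a_prev))
    if np.any(np.diff(nodes[:, 0]) <= 0):
        raise GenerationError("distortion curve too extreme; strips self-intersect")
    return nodes


def _bend_onto_curve(
    ab: np.ndarray, coeffs, n_seg: int, a_range: tuple | None = None,
    anchor: float | None = None,
) -> np.ndarray:
    """Map flat 2D points (a, b) onto the curve by inverting the
    segment-wise flattening: point with flat offset u in segment k gets
    q = R(-phi_k) (u - t_k, b) + node_k."""
    ab = np.asarray(ab, float)
    u = ab[:, 0]
    u0, u1 = a_range if a_range is not None else (u.min(), u.max())
    if u1 <= u0:
        raise GenerationError("degenerate flat range for distortion")
    seg_len = (u1 - u0) / n_seg
    nodes = _curve_nodes(coeffs, u0, seg_len, n_seg, anchor=anchor)
    seg = np.clip(((u - u0) / seg_len).astype(int), 0, n_seg - 1)
    deltas = np.diff(nodes, axis=0)
    phis = np.arctan2(deltas[:, 1], deltas[:, 0])   # -phi_k of the flattening
    # fold guard: points offset |b| from the skeleton collide where the
    # local turning radius seg_len/|dphi| drops below that offset
    b_extent = np.abs(ab[:, 1]).max() if len(ab) else 0.0
    dphi = np.abs(np.diff(phis)).max() if n_seg > 1 else 0.0
    if dphi > 0 and b_extent > seg_len / dphi:
        raise GenerationError(
            "distortion curve too extreme; strips would self-intersect"
        )
    out = np.empty_like(ab)
    for k in range(n_seg):
        m = seg == k
        if not m.any():
            continue
        c, s = np.cos(phis[k]), np.sin(phis[k])
        local = np.stack([u[m] - u0 - k * seg_len, ab[m, 1]], axis=1)
        out[m, 0] = c * local[:, 0] - s * local[:, 1] + nodes[k, 0]
        out[m, 1] = s * local[:, 0] + c * local[:, 1] + nodes[k, 1]
    return out


def apply_inverse_flattening(
    flat: PointCloud3,
    bend_coeffs,
    roll_coeffs,
    n_segments: int = 49,
    roll_profile=None,
) -> PointCloud3:
    """Distort a flat leaf (h = 0) by rolling then bending.

    Rolling maps each l-strip's (w, h) cross-section onto the cubic
    roll curve (optionally scaled by ``roll_profile(l_mid)``); bending
    then maps the whole cloud's (l, h) coordinates onto the quadratic
    vein curve. Both maps preserve arc length along their skeletons, so
    the distorted leaf flattens back to exactly the input's area.
    """
    coords = flat.coords.copy()
    if np.abs(coords[:, 2]).max() > 1e-12:
        raise ValueError("inverse flattening expects a flat (h = 0) cloud")
    l, w = coords[:, 0], coords[:, 1]
    l0, l1 = l.min(), l.max()
    w0, w1 = w.min(), w.max()

    # --- rolling, strip by strip along l
    if np.any(np.asarray(roll_coeffs)[1:] != 0):
        seg_len = (l1 - l0) / n_segments
        strip_id = np.clip(((l - l0) / seg_len).astype(int), 0, n_segments - 1)
        for k in range(n_segments):
            m = strip_id == k
            if not m.any():
                continue
            scale = 1.0 if roll_profile is None else float(
                roll_profile(l0 + (k + 0.5) * seg_len)
            )
            ck = tuple(scale * c for c in roll_coeffs)
            coords[m, 1:3] = _bend_onto_curve(
                coords[m, 1:3], ck, n_segments, a_range=(w0, w1), anchor=0.0
            )

    # --- bending, whole cloud (anchored at the sag apex so a symmetric
    # curve produces a symmetric leaf whose mean orientation matches the
    # declared true axes)
    bend_coeffs = np.asarray(bend_coeffs, float)
    if np.any(bend_coeffs[1:] != 0):
        anchor = None
        if len(bend_coeffs) >= 3 and bend_coeffs[2] != 0 and np.all(bend_coeffs[3:] == 0):
            anchor = float(-bend_coeffs[1] / (2.0 * bend_coeffs[2]))
        lh = coords[:, [0, 2]]
        coords[:, [0, 2]] = _bend_onto_curve(
            lh, bend_coeffs, n_segments, a_range=(l0, l1), anchor=anchor
        )
    return flat.with_coords(coords)


# ---------------------------------------------------------------------------
# Noise, holes, pose
# ---------------------------------------------------------------------------

def add_noise(
    cloud: PointCloud3, sigma: float, rng: np.random.Generator | int | None = None
) -> PointCloud3:
    """Isotropic Gaussian jitter with standard deviation ``sigma`` mm."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return cloud.with_coords(cloud.coords.copy())
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return cloud.with_coords(cloud.coords + rng.normal(0.0, sigma, cloud.coords.shape))


def punch_holes(cloud: PointCloud3, hole_specs) -> PointCloud3:
    """Delete points inside spheres (center, radius) — missing-point holes."""
    keep = np.ones(len(cloud), dtype=bool)
    for center, radius in hole_specs:
        center = np.asarray(center, float).reshape(3)
        keep &= np.linalg.norm(cloud.coords - center, axis=1) > radius
    if not keep.any():
        raise GenerationError("holes removed every point of the leaf")
    return cloud.select(keep)


def random_rigid_pose(
    cloud: PointCloud3,
    rng: np.random.Generator | int | None = None,
    min_normal_up: float = 0.15,
) -> tuple[PointCloud3, LeafAxes]:
    """Rotate the leaf about its base (the emergence point at the world
    origin) by a uniform random proper rotation and return the posed
    world-frame cloud together with the ground-truth leaf axes.

    Rotations leaving the leaf normal within ~8.6 degrees of horizontal
    (|h . z| < ``min_normal_up``) are resampled: the world-up
    disambiguation of the h-axis is undefined for a vertical leaf and a
    top-down scanner never sees one.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for _ in range(1000):
        rot = Rotation.random(random_state=rng).as_matrix()
        if abs(rot[2, 2]) >= min_normal_up:
            break
    else:       # pragma: no cover - p(failure) astronomically small
        raise GenerationError("could not draw a pose with a non-horizontal normal")
    posed = cloud.with_coords(cloud.coords @ rot.T, frame=WORLD)
    l_axis = rot[:, 0]
    h_axis = rot[:, 2]
    if h_axis[2] < 0:
        h_axis = -h_axis
    axes = compose_axes(l_axis, h_axis, posed.centroid)
    return posed, axes


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLeaf:
    """A generated leaf with every piece of ground truth a test needs."""

    world: PointCloud3          # scanner-style input for the pipeline
    leaf_truth: PointCloud3     # the same points in the true leaf frame
    flat: PointCloud3           # undistorted flat cloud (pre-noise/holes)
    true_area: float            # analytic flat area, mm^2
    axes: LeafAxes              # ground-truth (l, w, h) + centroid
    spec: SyntheticLeafSpec


def generate_leaf(spec: SyntheticLeafSpec) -> SyntheticLeaf:
    """Flat sampling -> inverse-flattening distortion -> holes -> noise
    -> optional rigid pose. Fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    flat, area = make_flat_leaf(spec, rng)
    distorted = apply_inverse_flattening(
        flat, spec.resolved_bend_coeffs(), spec.resolved_roll_coeffs(),
        n_segments=spec.n_segments,
    )
    if spec.n_holes > 0 and spec.hole_radius > 0:
        centers = distorted.coords[
            rng.choice(len(distorted), size=spec.n_holes, replace=False)
        ]
        distorted = punch_holes(
            distorted, [(c, spec.hole_radius) for c in centers]
        )
    noisy = add_noise(distorted, spec.noise_sigma, rng)
    if spec.apply_pose:
        world, axes = random_rigid_pose(noisy, rng)
    else:
        world = noisy.with_coords(noisy.coords.copy(), frame=WORLD)
        axes = compose_axes(
            np.array([1.0, 0, 0]), np.array([0, 0, 1.0]), world.centroid
        )
    leaf_truth = to_leaf_frame(world, axes)
    return SyntheticLeaf(world, leaf_truth, flat, area, axes, spec)


def generate_time_series(
    base_spec: SyntheticLeafSpec,
    n_frames: int,
    growth_rate: float = 0.01,
    seed: int = 0,
):
    """A linearly growing leaf sequence with exact ground-truth areas.

    Frame t scales length and width by sqrt(1 + growth_rate * t) (and
    the distortion amplitudes with them), so the true flat area follows
    area_0 * (1 + growth_rate * t) — an exactly linear trend. Noise is
    drawn independently per frame.

    Returns ``(leaves, true_areas)``.
    """
    if n_frames < 2:
        raise ValueError("a series needs at least 2 frames")
    leaves = []
    areas = np.empty(n_frames)
    for t in range(n_frames):
        s = float(np.sqrt(1.0 + growth_rate * t))
        spec_t = dataclasses.replace(
            base_spec,
            length=base_spec.length * s,
            max_width=base_spec.max_width * s,
            bend_sag=base_spec.bend_sag * s,
            roll_amplitude=base_spec.roll_amplitude * s,
            bend_coeffs=None,
            roll_coeffs=None,
            seed=(seed + 7919 * t) % (2**31 - 1),
        )
        leaf = generate_leaf(spec_t)
        leaves.append(leaf)
        areas[t] = leaf.true_area
    return leaves, areas
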