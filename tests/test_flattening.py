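"""Piecewise skeleton flattening: isometry, strips, alignment, shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

import leafsurf as ls
from leafsurf.flattening import _rot
from leafsurf.skeleton import BENDING_PLANE, ROLLING_PLANE, Skeleton
from leafsurf.synthetic import _curve_nodes


def _skeleton_from_points(points, plane=BENDING_PLANE):
    pts = np.asarray(points, float)
    return Skeleton(pts, np.zeros(1), plane, (pts[0, 0], pts[-1, 0]))


def _leaf_cloud(coords):
    return ls.PointCloud3(np.asarray(coords, float), frame="leaf")


# ---------------------------------------------------------------------------
# segment angle
# ---------------------------------------------------------------------------

def test_horizontal_segment_angle_zero():
    assert ls.segment_angle([0, 0], [1, 0]) == 0.0


def test_vertical_segment_quarter_turn():
    phi = ls.segment_angle([0, 0], [0, 1])
    assert phi == pytest.approx(-np.pi / 2)
    np.testing.assert_allclose(_rot(phi) @ [0, 1], [1, 0], atol=1e-15)


def test_coincident_points_rejected():
    with pytest.raises(ls.DegenerateSegmentError):
        ls.segment_angle([1, 2], [1, 2])


@settings(max_examples=200, derandomize=True)
@given(
    dx=st.floats(-100, 100, allow_nan=False),
    dy=st.floats(-100, 100, allow_nan=False),
)
def test_rotation_lands_segment_on_positive_a_axis(dx, dy):
    n = np.hypot(dx, dy)
    if n < 1e-9:
        return
    phi = ls.segment_angle([0, 0], [dx, dy])
    assert -np.pi < phi <= np.pi
    rotated = _rot(phi) @ [dx, dy]
    assert abs(rotated[1]) < 1e-9 * max(1.0, n)
    assert rotated[0] > 0


# ---------------------------------------------------------------------------
# flatten_skeleton
# ---------------------------------------------------------------------------

def test_straight_skeleton_is_identity_up_to_shift(rng):
    a = np.linspace(2.0, 42.0, 9)
    skel = _skeleton_from_points(np.column_stack([a, np.zeros(9)]))
    coords = np.column_stack([
        rng.uniform(2, 42, 200), rng.uniform(-5, 5, 200), rng.uniform(-1, 1, 200)
    ])
    flat_skel, strips = ls.flatten_skeleton(skel, _leaf_cloud(coords))
    np.testing.assert_allclose(flat_skel.points[:, 0], a - a[0], atol=1e-12)
    assert strips.dropped_count == 0
    union = strips.union()
    order = np.argsort(union.index)
    got = union.coords[order]
    expected = coords.copy()
    expected[:, 0] -= a[0]
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_right_angle_two_segment_case():
    # skeleton: (0,0) -> (1,0) -> (1,1); flattened span = 2, all on a-axis
    skel = _skeleton_from_points([[0, 0], [1, 0], [1, 1]])
    cloud = _leaf_cloud(np.array([[0.5, 0.0, 0.3], [1.0, 0.5, 0.7]]))
    flat_skel, strips = ls.flatten_skeleton(skel, cloud)
    np.testing.assert_allclose(flat_skel.points, [[0, 0], [1, 0], [2, 0]], atol=1e-12)
    # point at (l=1, h=0.7), 0.7 up the vertical arm, unrolls to a = 1 + 0.7
    np.testing.assert_allclose(strips.strips[1].coords[0], [1.7, 0.5, 0.0], atol=1e-12)


def test_single_point_skeleton_rejected():
    with pytest.raises(ValueError):
        Skeleton(np.array([[0.0, 0.0]]), np.zeros(1), BENDING_PLANE, (0, 0))


def test_chord_conservation_and_collinearity(rng):
    for _ in range(200):
        n = rng.integers(3, 12)
        a = np.cumsum(rng.uniform(0.2, 2.0, n))
        b = rng.normal(0, 3.0, n)
        skel = _skeleton_from_points(np.column_stack([a, b]))
        flat_skel, _ = ls.flatten_skeleton(skel, _leaf_cloud(np.empty((0, 3))))
        assert np.abs(flat_skel.points[:, 1]).max() < 1e-9
        chords = np.linalg.norm(np.diff(skel.points, axis=0), axis=1)
        np.testing.assert_allclose(flat_skel.segment_lengths, chords, atol=1e-9)
        # s'_0 at origin, a-components non-decreasing
        assert np.all(flat_skel.points[0] == 0)
        assert np.all(np.diff(flat_skel.points[:, 0]) > 0)


def test_strip_partition_covers_input(rng, leaf_frame_cloud):
    skel = ls.extract_skeleton(leaf_frame_cloud, BENDING_PLANE, expand_frac=0.05)
    _, strips = ls.flatten_skeleton(skel, leaf_frame_cloud)
    ids = [s.index for s in strips.strips if len(s)]
    all_ids = np.concatenate(ids + [strips.dropped])
    assert len(all_ids) == len(np.unique(all_ids)) == len(leaf_frame_cloud)


def test_inverse_flattening_roundtrip_is_exact(rng):
    """Flattening with the generator's own curve nodes as the skeleton
    undoes the inverse-flattening distortion point for point."""
    flat, _ = ls.make_flat_leaf(ls.SyntheticLeafSpec(density=1.0, seed=5))
    coeffs = (0.0, 0.4, -0.004)
    distorted = ls.apply_inverse_flattening(flat, coeffs, (0.0, 0.0, 0.0, 0.0), 20)
    l = flat.coords[:, 0]
    seg = (l.max() - l.min()) / 20
    nodes = _curve_nodes(coeffs, l.min(), seg, 20, anchor=-0.4 / (2 * -0.004))
    skel = _skeleton_from_points(nodes)
    _, strips = ls.flatten_skeleton(skel, distorted)
    assert strips.dropped_count == 0
    union = strips.union()
    order = np.argsort(union.index)
    expected = flat.coords.copy()
    expected[:, 0] -= l.min()
    np.testing.assert_allclose(union.coords[order], expected, atol=1e-6)


# ---------------------------------------------------------------------------
# bending
# ---------------------------------------------------------------------------

def test_planar_leaf_bending_is_identity(flat_rectangle):
    leaf = flat_rectangle.with_coords(flat_rectangle.coords, frame="leaf")
    res = ls.flatten_bending(leaf)
    order = np.argsort(res.flattened.index)
    got = res.flattened.coords[order]
    expected = leaf.coords.copy()
    expected[:, 0] -= res.raw_skeleton.points[0, 0]
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_bending_removes_most_vein_distortion():
    spec = ls.SyntheticLeafSpec(density=2, bend_sag=20, roll_amplitude=0, seed=2)
    leaf = ls.generate_leaf(spec)
    res = ls.flatten_bending(leaf.leaf_truth)
    before = np.abs(leaf.leaf_truth.coords[:, 2]).mean()
    after = np.abs(res.flattened.coords[:, 2]).mean()
    assert after < 0.05 * before


def test_strip_count_bounded_by_skeleton(leaf_frame_cloud):
    res = ls.flatten_bending(leaf_frame_cloud, n_points=50)
    assert len(res.strips.strips) == 49
    assert res.strips.dropped_count >= 0


# ---------------------------------------------------------------------------
# alignment skeleton and landmarks
# ---------------------------------------------------------------------------

def test_symmetric_leaf_midline_near_zero(rng):
    cloud = _leaf_cloud(np.column_stack([
        rng.uniform(0, 60, 2000), rng.uniform(-10, 10, 2000), np.zeros(2000)
    ]))
    skel = ls.compute_alignment_skeleton(cloud)
    assert np.abs(skel.points[:, 1]).max() < 0.5


def test_offset_leaf_midline_shifted(rng):
    cloud = _leaf_cloud(np.column_stack([
        rng.uniform(0, 60, 2000), 3.0 + rng.uniform(-10, 10, 2000), np.zeros(2000)
    ]))
    skel = ls.compute_alignment_skeleton(cloud)
    np.testing.assert_allclose(skel.points[:, 1], 3.0, atol=0.5)


def test_cubic_midline_recovered_noiseless(rng):
    l = rng.uniform(0, 50, 500)
    cloud = _leaf_cloud(np.column_stack([l, 0.001 * l**3, np.zeros(500)]))
    skel = ls.compute_alignment_skeleton(cloud)
    np.testing.assert_allclose(
        skel.points[:, 1], 0.001 * skel.points[:, 0] ** 3, atol=1e-3
    )


def test_landmark_picks_nearest_w():
    pts = np.column_stack([np.linspace(-2, 2, 9), np.zeros(9)])
    skel = Skeleton(pts, np.zeros(1), ROLLING_PLANE, (-2, 2))
    idx = ls.find_landmark(skel, np.array([10.0, 0.0]), (9.0, 11.0))
    assert idx == 4  # w closest to 0


def test_landmark_tie_breaks_to_lower_index():
    pts = np.array([[-1.0, 0.0], [1.0, 0.0]])
    skel = Skeleton(pts, np.zeros(1), ROLLING_PLANE, (-1, 1))
    assert ls.find_landmark(skel, np.array([5.0, 0.0]), (4.0, 6.0)) == 0


def test_landmark_matches_exhaustive_oracle(rng):
    for _ in range(50):
        n = rng.integers(3, 20)
        pts = np.column_stack([np.sort(rng.uniform(-5, 5, n)), rng.normal(0, 2, n)])
        pts[:, 0] += np.arange(n) * 1e-6  # ensure strictly increasing
        skel = Skeleton(pts, np.zeros(1), ROLLING_PLANE, (pts[0, 0], pts[-1, 0]))
        anchor = rng.uniform(-5, 5, 2)      # (l, w)
        l_range = tuple(np.sort(rng.uniform(-10, 10, 2)))
        l_mid = np.mean(l_range)
        d = [
            (p[0] - anchor[1]) ** 2 + p[1] ** 2 + (l_mid - anchor[0]) ** 2
            for p in pts
        ]
        assert ls.find_landmark(skel, anchor, l_range) == int(np.argmin(d))


# ---------------------------------------------------------------------------
# rolling and shape
# ---------------------------------------------------------------------------

def test_flat_strips_give_continuous_union(flat_rectangle):
    leaf = flat_rectangle.with_coords(flat_rectangle.coords, frame="leaf")
    bend = ls.flatten_bending(leaf)
    roll = ls.flatten_rolling(bend.strips, leaf)
    # straight midline at w=0: alignment shifts stay small and the union
    # has no strip-to-strip w jumps
    mids = [
        0.5 * (s.coords[:, 1].min() + s.coords[:, 1].max())
        for s in roll.strips if s is not None and len(s) > 10
    ]
    assert np.abs(mids).max() < 1.0
    assert np.abs(roll.flattened.coords[:, 2]).max() < 1e-9


def test_rolling_removes_cross_section_distortion():
    spec = ls.SyntheticLeafSpec(density=3, bend_sag=20, roll_amplitude=8, seed=4)
    leaf = ls.generate_leaf(spec)
    bend = ls.flatten_bending(leaf.leaf_truth)
    roll = ls.flatten_rolling(bend.strips, leaf.leaf_truth)
    h_before = np.abs(bend.flattened.coords[:, 2]).mean()
    h_after = np.abs(roll.flattened.coords[:, 2]).mean()
    assert h_after < 0.10 * h_before


def test_distortion_monotone_through_pipeline(bent_leaf):
    res = ls.flatten_leaf(bent_leaf.world)
    d = res.distortion
    assert d["P"].mean > d["P'"].mean > d["P''"].mean


def test_sparse_strips_are_skipped_and_logged():
    spec = ls.SyntheticLeafSpec(density=0.35, bend_sag=10, roll_amplitude=3, seed=6)
    leaf = ls.generate_leaf(spec)
    res = ls.flatten_leaf(leaf.world)
    assert len(res.rolling.skipped) > 0
    for k in res.rolling.skipped:
        assert res.rolling.strips[k] is None


def test_shape_point_count_matches_flattened(bent_leaf):
    res = ls.flatten_leaf(bent_leaf.world)
    assert len(res.shape.points) == len(res.rolling.flattened)


def test_flat_rectangle_end_to_end_identity(flat_rectangle):
    res = ls.flatten_leaf(flat_rectangle)
    spans = np.ptp(res.shape.points, axis=0)
    np.testing.assert_allclose(sorted(spans), [30.0, 80.0], atol=1e-6)
    assert np.abs(res.rolling.flattened.coords[:, 2]).max() < 1e-6


def test_recovered_outline_close_to_flat_truth(bent_leaf):
    """Symmetric Hausdorff distance between the recovered flat shape and
    the generator's flat cloud stays below 2% of leaf length."""
    res = ls.flatten_leaf(bent_leaf.world)
    got = res.shape.points - res.shape.points.mean(axis=0)
    truth = bent_leaf.flat.coords[:, :2]
    truth = truth - truth.mean(axis=0)
    # w-axis sign of the recovered frame is convention-dependent
    best = np.inf
    for sign in (1.0, -1.0):
        g = got * np.array([1.0, sign])
        d1 = cKDTree(truth).query(g)[0].max()
        d2 = cKDTree(g).query(truth)[0].max()
        best = min(best, max(d1, d2))
    assert best < 0.02 * bent_leaf.spec.length
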