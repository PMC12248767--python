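"""Convex hulls, polygon intersection, and the overlap-index filter."""

from __future__ import annotations

import numpy as np
import pytest

from nucalign import (
    DegeneratePolygonError,
    NucleusPolygon,
    OverlapScore,
    convex_hull,
    intersection_area,
    normalize_pair,
    overlap_decision,
    overlap_indexes,
    polygon_filter,
)


def monte_carlo_intersection(pa, pb, n_samples: int, seed: int) -> float:
    """Rasterization oracle: sample the joint bounding box uniformly and
    count points inside both polygons (half-plane test, no shapely)."""
    rng = np.random.default_rng(seed)
    verts = np.vstack([pa.vertices, pb.vertices])
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    pts = rng.uniform(lo, hi, (n_samples, 2))
    box_area = np.prod(hi - lo)
    inside = _inside_convex(pts, pa.vertices) & _inside_convex(pts, pb.vertices)
    return float(inside.mean() * box_area)


def _inside_convex(pts: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Point-in-convex-polygon by cross products against each CCW edge."""
    ok = np.ones(len(pts), dtype=bool)
    for a, b in zip(verts, np.roll(verts, -1, axis=0)):
        edge = b - a
        rel = pts - a
        ok &= edge[0] * rel[:, 1] - edge[1] * rel[:, 0] >= -1e-12
    return ok


def random_convex_polygon(rng: np.random.Generator) -> NucleusPolygon:
    pts = rng.uniform(0, 20, (rng.integers(4, 15), 2))
    return convex_hull(pts)


def square(side: float, offset=(0.0, 0.0)) -> NucleusPolygon:
    ox, oy = offset
    return NucleusPolygon(
        [(ox, oy), (ox + side, oy), (ox + side, oy + side), (ox, oy + side)]
    )


class TestConvexHull:
    def test_interior_point_absorbed(self):
        hull = convex_hull([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)])
        assert len(hull.vertices) == 4
        assert hull.area == pytest.approx(1.0)

    def test_triangle_area_by_shoelace(self):
        hull = convex_hull([(0, 0), (4, 0), (0, 3)])
        assert len(hull.vertices) == 3
        assert hull.area == pytest.approx(6.0)

    def test_ccw_orientation(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert random_convex_polygon(rng).area > 0

    def test_all_points_inside_hull(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, (50, 2))
        hull = convex_hull(pts)
        assert _inside_convex(pts, hull.vertices).all()

    @pytest.mark.parametrize(
        "points", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2), (3, 3)]]
    )
    def test_degenerate_input_signalled(self, points):
        with pytest.raises(DegeneratePolygonError):
            convex_hull(points)


class TestNormalizePair:
    def test_identity_scale_centers_both(self):
        a, b = square(2.0, (5, 7)), square(2.0, (-3, 4))
        na, nb = normalize_pair(a, b, (1.0, 1.0))
        np.testing.assert_allclose(na.vertices, nb.vertices)
        for p in (na, nb):
            mids = (p.vertices.min(axis=0) + p.vertices.max(axis=0)) / 2
            np.testing.assert_allclose(mids, 0.0, atol=1e-12)

    def test_scaling_equalizes_proportional_squares(self):
        he, dapi = square(2.0), square(4.0, (10, 10))
        na, nb = normalize_pair(he, dapi, (2.0, 2.0))
        assert intersection_area(na, nb) == pytest.approx(16.0)

    def test_bbox_midpoint_at_origin_for_any_pair(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            na, nb = normalize_pair(
                random_convex_polygon(rng), random_convex_polygon(rng), (1.3, 0.7)
            )
            for p in (na, nb):
                mids = (p.vertices.min(axis=0) + p.vertices.max(axis=0)) / 2
                np.testing.assert_allclose(mids, 0.0, atol=1e-9)


class TestIntersectionArea:
    def test_identical_unit_squares(self):
        assert intersection_area(square(1.0), square(1.0)) == pytest.approx(1.0)

    def test_disjoint_squares(self):
        assert intersection_area(square(1.0), square(1.0, (5, 5))) == 0.0

    def test_half_overlapping_unit_squares(self):
        assert intersection_area(
            square(1.0), square(1.0, (0.5, 0.0))
        ) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pa, pb = random_convex_polygon(rng), random_convex_polygon(rng)
            ab, ba = intersection_area(pa, pb), intersection_area(pb, pa)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert ab <= min(pa.area, pb.area) + 1e-12

    def test_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(4)
        for k in range(25):
            pa, pb = random_convex_polygon(rng), random_convex_polygon(rng)
            exact = intersection_area(pa, pb)
            mc = monte_carlo_intersection(pa, pb, 100_000, seed=k)
            assert abs(exact - mc) <= 0.01 * max(pa.area, pb.area)


class TestOverlapIndexes:
    def test_identical_polygons_score_one(self):
        score = overlap_indexes(square(3.0), square(3.0))
        assert score.index_avg == pytest.approx(1.0)
        assert score.index_min == pytest.approx(1.0)

    def test_concentric_squares(self):
        """Areas 1 and 0.25: avg = (0.25/1 + 0.25/0.25)/2, min = 0.25."""
        outer = square(1.0)
        inner = square(0.5, (0.25, 0.25))
        score = overlap_indexes(outer, inner)
        assert score.intersection_area == pytest.approx(0.25)
        assert score.index_avg == pytest.approx(0.625)
        assert score.index_min == pytest.approx(0.25)

    def test_disjoint_scores_zero(self):
        score = overlap_indexes(square(1.0), square(1.0, (9, 9)))
        assert score.index_avg == 0.0 and score.index_min == 0.0

    def test_min_never_exceeds_avg(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            score = overlap_indexes(
                random_convex_polygon(rng), random_convex_polygon(rng)
            )
            assert score.index_min <= score.index_avg + 1e-12
            assert 0.0 <= score.index_min and score.index_avg <= 1.0 + 1e-12


class TestFilterDecisions:
    @pytest.mark.parametrize("index_avg", [0.755, 0.847])
    def test_low_average_indexes_removed_at_default_threshold(self, index_avg):
        """Indexes below 0.9 mark nuclei of inconsistent shape; removed."""
        score = OverlapScore(np.nan, index_avg=index_avg, index_min=index_avg)
        assert not overlap_decision(score, "average", 0.9)

    def test_threshold_is_inclusive_on_keep_side(self):
        score = OverlapScore(np.nan, index_avg=0.9, index_min=0.9)
        assert overlap_decision(score, "average", 0.9)
        assert overlap_decision(score, "minimum", 0.9)

    def test_min_mode_pass_implies_avg_pass(self):
        """Any pair kept at minimum-threshold 0.92 also passes average 0.92."""
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(200):
            pa = random_convex_polygon(rng)
            jitter = pa.vertices + rng.normal(0, 0.15, pa.vertices.shape)
            try:
                pb = convex_hull(jitter)
            except DegeneratePolygonError:
                continue
            score = overlap_indexes(pa, pb)
            if overlap_decision(score, "minimum", 0.92):
                checked += 1
                assert overlap_decision(score, "average", 0.92)
        assert checked > 10

    def test_polygon_filter_end_to_end(self):
        sq = [(0, 0), (4, 0), (4, 4), (0, 4)]
        sliver = [(0, 0), (4, 0), (4, 0.5), (0, 0.5)]
        degenerate = [(0, 0), (1, 1), (2, 2)]
        pairs = [
            ("match", sq, [(10, 10), (14, 10), (14, 14), (10, 14)]),
            ("shape_mismatch", sq, sliver),
            ("degenerate", sq, degenerate),
        ]
        kept = polygon_filter(pairs, mode="average", threshold=0.9, scale=(1, 1))
        assert kept == ["match"]
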