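"""Center mapping, search regions, directional crops and PSNR consensus."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nucalign import (
    GrayImage,
    NucleusRecord,
    SearchRegion,
    build_search_region,
    consensus_match,
    crop_directional_patches,
    load_dapi_nuclei,
    labels_to_nuclei,
    map_center,
    psnr,
    render_he_patch_for_psnr,
    segment_he,
)
from nucalign.patches import DIRECTIONS, stretch_contrast
from nucalign.segmentation import SegmentationResult


class TestMapCenter:
    @pytest.mark.parametrize(
        "point, he_dims, dapi_dims, expected",
        [
            ((50, 50), (100, 100), (200, 200), (100.0, 100.0)),
            ((0, 0), (123, 456), (789, 1011), (0.0, 0.0)),
            ((25, 75), (100, 200), (300, 100), (75.0, 37.5)),
        ],
    )
    def test_proportional_mapping(self, point, he_dims, dapi_dims, expected):
        assert map_center(point, he_dims, dapi_dims) == expected

    def test_corners_map_to_corners(self):
        he, dapi = (120, 80), (300, 500)
        assert map_center((120, 80), he, dapi) == (300.0, 500.0)

    def test_linearity(self):
        he, dapi = (100, 200), (250, 300)
        p1, p2 = np.array([10.0, 20.0]), np.array([30.0, 50.0])
        m1 = np.array(map_center(tuple(p1), he, dapi))
        m2 = np.array(map_center(tuple(p2), he, dapi))
        mid = np.array(map_center(tuple((p1 + p2) / 2), he, dapi))
        np.testing.assert_allclose(mid, (m1 + m2) / 2)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            map_center((150, 50), (100, 100), (200, 200))


def _point_nuclei(centers):
    """Diamond boundaries whose bounding-box midpoint is exactly the center."""
    diamond = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, -1.0], [0.0, 1.0]])
    return [
        NucleusRecord(i, "DAPI", c + diamond)
        for i, c in enumerate(np.asarray(centers, dtype=float))
    ]


class TestSearchRegion:
    def test_radius_is_ratio_of_min_dimension(self):
        nuclei = _point_nuclei(np.random.default_rng(0).uniform(0, 900, (200, 2)))
        region = build_search_region((500, 500), 0.5, (1000, 2000), nuclei, 1)
        assert region.radius == 500.0

    def test_membership_is_square_rule(self):
        nuclei = _point_nuclei([(99, 100), (161, 100), (100, 161), (160, 160)])
        region = build_search_region((100, 100), 0.06, (1000, 1000), nuclei, 1)
        # radius 60, inclusive: (161,100) and (100,161) miss by 1 px on one
        # axis; (160,160) sits exactly on the corner and is kept
        assert region.member_ids == [0, 3]

    @pytest.mark.parametrize("n, kept", [(2060, True), (50, True), (49, False)])
    def test_min_cell_threshold(self, n, kept):
        rng = np.random.default_rng(1)
        nuclei = _point_nuclei(rng.uniform(450, 550, (n, 2)))
        region = build_search_region((500, 500), 0.5, (1000, 1000), nuclei, 50)
        assert (region is not None) == kept
        if kept:
            assert len(region.member_ids) == n


class TestDirectionalCrops:
    def test_offset_arithmetic(self):
        """Directional windows are the center window displaced by the move."""
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 255, (2000, 2000))
        r, m, cx, cy = 400, 300, 1000, 1000
        patches = crop_directional_patches(img, (cx, cy), r, m, patch_size=32)
        assert set(patches) == set(DIRECTIONS)
        expected_centers = {
            "center": (cx, cy),
            "up": (cx, cy - m),
            "down": (cx, cy + m),
            "left": (cx - m, cy),
            "right": (cx + m, cy),
        }
        from nucalign.images import resize_bilinear

        for d, (px, py) in expected_centers.items():
            window = img[py - r : py + r, px - r : px + r]
            np.testing.assert_allclose(patches[d], resize_bilinear(window, (32, 32)))

    def test_out_of_bounds_rejected(self):
        img = np.zeros((2000, 2000))
        assert crop_directional_patches(img, (100, 100), 400, 300) is None

    def test_constant_image_gives_constant_patches(self):
        img = np.full((1000, 1000), 37.0)
        patches = crop_directional_patches(img, (500, 500), 100, 80, patch_size=32)
        for p in patches.values():
            np.testing.assert_allclose(p, 37.0)

    def test_anisotropic_radius(self):
        img = np.zeros((400, 400))
        patches = crop_directional_patches(img, (200, 200), (50, 30), (10, 5), 16)
        assert patches is not None


class TestPsnr:
    def test_identical_patches_are_infinite(self):
        a = np.random.default_rng(0).uniform(0, 255, (8, 8))
        assert psnr(a, a) == math.inf

    def test_full_scale_difference_is_zero_db(self):
        a, b = np.zeros((4, 4)), np.full((4, 4), 255.0)
        assert psnr(a, b, 255.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_pixel_difference_2x2(self):
        a = np.zeros((2, 2))
        b = np.zeros((2, 2))
        b[0, 0] = 255.0
        # MSE = 255^2/4, so PSNR = 10*log10(4)
        assert psnr(a, b, 255.0) == pytest.approx(10 * math.log10(4), abs=1e-9)

    def test_strictly_decreasing_in_mse(self):
        rng = np.random.default_rng(7)
        scored = []
        for _ in range(200):
            a = rng.uniform(0, 255, (6, 6))
            b = rng.uniform(0, 255, (6, 6))
            from nucalign import mse

            scored.append((mse(a, b), psnr(a, b)))
        scored.sort()
        for (m1, p1), (m2, p2) in zip(scored, scored[1:]):
            if m2 > m1:
                assert p2 < p1


class TestHeRendering:
    def test_background_and_interior_crops(self):
        img = np.zeros((600, 600), dtype=int)
        img[200:400, 200:400] = 5
        seg = SegmentationResult(img, "ground_truth")
        patches = render_he_patch_for_psnr(seg, (300, 300), 40, 0, 32)
        np.testing.assert_allclose(patches["center"], 255.0)
        patches = render_he_patch_for_psnr(seg, (100, 100), 40, 0, 32)
        np.testing.assert_allclose(patches["center"], 0.0)

    def test_foreground_fraction_survives_resize(self, small_scene):
        seg = SegmentationResult(small_scene.label_image, "ground_truth")
        r = 40
        rec = patches = None
        for rec in labels_to_nuclei(seg):
            patches = render_he_patch_for_psnr(seg, rec.center, r, 0, 224)
            if patches is not None:
                break
        assert patches is not None
        cx, cy = int(round(rec.center[0])), int(round(rec.center[1]))
        window = small_scene.label_image[cy - r : cy + r, cx - r : cx + r]
        before = (window > 0).mean()
        after = (patches["center"] > 127).mean()
        assert abs(before - after) < 0.02


def _blob_image():
    """A DAPI-like image with two differently shaped nuclei."""
    img = np.full((400, 400), 10.0)
    img[90:110, 85:115] = 220.0  # candidate a at (100, 100)
    img[295:305, 290:310] = 240.0  # candidate b at (300, 300)
    return GrayImage(img)


def _candidates():
    a = NucleusRecord("a", "DAPI", [(85, 90), (115, 90), (115, 110), (85, 110)])
    b = NucleusRecord("b", "DAPI", [(290, 295), (310, 295), (310, 305), (290, 305)])
    return {"a": a, "b": b}


class TestConsensus:
    def test_single_candidate_identical_patches(self):
        dapi = _blob_image()
        cands = _candidates()
        region = SearchRegion((100, 100), 80, ["a"])
        he_patches = crop_directional_patches(dapi, (100, 100), 40, 30, 64)
        he_patches = {d: stretch_contrast(p) for d, p in he_patches.items()}
        match = consensus_match(
            he_patches, 1, region, dapi, cands, 40, 30, 64
        )
        assert match is not None and match.consensus
        assert match.dapi_id == "a"
        assert all(v == math.inf for v in match.psnr_by_direction.values())

    def test_four_one_split_yields_none(self):
        """A candidate winning 4 of 5 directions is not a consensus match."""
        dapi = _blob_image()
        cands = _candidates()
        region = SearchRegion((200, 200), 200, ["a", "b"])
        pa = crop_directional_patches(dapi, (100, 100), 40, 30, 64)
        pb = crop_directional_patches(dapi, (300, 300), 40, 30, 64)
        he_patches = {d: stretch_contrast(pa[d]) for d in DIRECTIONS}
        he_patches["right"] = stretch_contrast(pb["right"])
        match = consensus_match(he_patches, 1, region, dapi, cands, 40, 30, 64)
        assert match is None

    def test_zero_move_distance_collapses_directions(self):
        """With move 0 all five directions coincide, so any winner is consensus."""
        dapi = _blob_image()
        cands = _candidates()
        region = SearchRegion((200, 200), 200, ["a", "b"])
        pa = crop_directional_patches(dapi, (100, 100), 40, 0, 64)
        he_patches = {d: stretch_contrast(p) for d, p in pa.items()}
        match = consensus_match(he_patches, 1, region, dapi, cands, 40, 0, 64)
        assert match is not None and match.dapi_id == "a"

    def test_winner_always_inside_region(self):
        dapi = _blob_image()
        cands = _candidates()
        region = SearchRegion((100, 100), 80, ["a"])  # b excluded
        pb = crop_directional_patches(dapi, (300, 300), 40, 30, 64)
        he_patches = {d: stretch_contrast(p) for d, p in pb.items()}
        match = consensus_match(he_patches, 1, region, dapi, cands, 40, 30, 64)
        assert match is None or match.dapi_id in region.member_ids

    def test_planted_counterparts_win_on_fixture(self, small_scene):
        """On an exact-correspondence scene the planted nucleus wins >= 90%."""
        seg = segment_he(
            small_scene.he_rgb,
            backend="ground_truth",
            backend_params={"label_image": small_scene.label_image},
        )
        he_recs = labels_to_nuclei(seg)
        dapi_recs = load_dapi_nuclei(small_scene.boundary_table)
        dapi_by_id = {r.id: r for r in dapi_recs}
        truth = dict(
            zip(small_scene.correspondences.he_label, small_scene.correspondences.dapi_id)
        )
        radius, move = 30, 22
        from nucalign.patches import render_binary_labels

        render = render_binary_labels(seg)
        cache: dict = {}
        tried = correct = 0
        for rec in he_recs:
            if tried >= 25:
                break
            he_patches = crop_directional_patches(render, rec.center, radius, move, 64)
            if he_patches is None:
                continue
            region = build_search_region(
                rec.center, 0.5, (300, 450), dapi_recs, 50
            )
            if region is None:
                continue
            tried += 1
            match = consensus_match(
                he_patches, rec.id, region, small_scene.dapi, dapi_by_id,
                radius, move, 64, patch_cache=cache,
            )
            if match is not None and match.dapi_id == truth[rec.id]:
                correct += 1
        assert tried >= 15
        assert correct / tried >= 0.9
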