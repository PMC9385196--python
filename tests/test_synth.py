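"""Synthetic scene generation, rasterization and annotation round trips."""

import json

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from cls_seg.roi import Box
from cls_seg.synth import (AnnotatedImage, LabelMeError, SceneSpec,
                           generate_scene, polygon_mask, rasterize_lesions,
                           read_labelme, sample_scene_specs, write_labelme)


class TestGenerateScene:
    def test_deterministic_in_spec_and_seed(self):
        spec = SceneSpec(canvas_width=320, canvas_height=240, seed=5)
        a, b = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(a.image, b.image)
        assert a.cervix_box == b.cervix_box
        for (pa, la), (pb, lb) in zip(a.lesions, b.lesions):
            assert la == lb and np.array_equal(pa, pb)

    def test_different_seeds_differ(self):
        a = generate_scene(SceneSpec(canvas_width=320, canvas_height=240, seed=1))
        b = generate_scene(SceneSpec(canvas_width=320, canvas_height=240, seed=2))
        assert not np.array_equal(a.image, b.image)

    def test_no_lesions_gives_empty_list(self):
        ann = generate_scene(SceneSpec(canvas_width=320, canvas_height=240,
                                       seed=3, n_lesions=0))
        assert ann.lesions == []
        assert not rasterize_lesions(ann).any()

    def test_default_canvas_is_full_resolution_4_3(self):
        spec = SceneSpec(seed=0)
        assert (spec.canvas_width, spec.canvas_height) == (2656, 1992)
        assert spec.canvas_width * 3 == spec.canvas_height * 4
        ann = generate_scene(spec)
        assert ann.image.shape == (1992, 2656, 3)

    @pytest.mark.parametrize("field,value", [
        ("n_lesions", -1), ("n_distractors", -2), ("n_speckles", -1),
        ("canvas_width", 0), ("lesion_scale", -3.0), ("noise_sd", -1.0),
        ("cervix_axes", (0.0, 50.0)),
    ])
    def test_invalid_spec_names_field(self, field, value):
        spec = SceneSpec(**{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            generate_scene(spec)

    def test_lesions_and_vertices_inside_cervix_box(self):
        for spec in sample_scene_specs(10, 42, canvas=(512, 384)):
            ann = generate_scene(spec)
            b = ann.cervix_box
            h, w = ann.image.shape[:2]
            for poly, _ in ann.lesions:
                assert poly.shape[0] >= 3
                assert (poly[:, 0] >= 0).all() and (poly[:, 0] < w).all()
                assert (poly[:, 1] >= 0).all() and (poly[:, 1] < h).all()
            mask = rasterize_lesions(ann)
            outside = mask.copy()
            outside[b.y:b.y + b.h, b.x:b.x + b.w] = False
            assert not outside.any()

    def test_mask_area_matches_analytic_polygon_area(self):
        # shoelace area of the annotation polygons vs rasterized pixel count
        for spec in sample_scene_specs(50, 1234, canvas=(320, 240)):
            ann = generate_scene(spec)
            analytic = 0.0
            for poly, _ in ann.lesions:
                x, y = poly[:, 0], poly[:, 1]
                analytic += 0.5 * abs(np.dot(x, np.roll(y, -1))
                                      - np.dot(y, np.roll(x, -1)))
            pixels = rasterize_lesions(ann).sum()
            if analytic > 0:
                assert pixels <= 4 * analytic
                assert pixels >= analytic / 4

    def test_speckles_bright_and_unsaturated(self):
        quiet = SceneSpec(canvas_width=320, canvas_height=240, seed=9,
                          n_lesions=0, n_speckles=0, noise_sd=0.0,
                          confuser_prob=0.0, n_distractors=0)
        speckled = SceneSpec(canvas_width=320, canvas_height=240, seed=9,
                             n_lesions=0, n_speckles=20, noise_sd=0.0,
                             confuser_prob=0.0, n_distractors=0)
        a = generate_scene(quiet).image.astype(int)
        b = generate_scene(speckled).image.astype(int)
        changed = (a != b).any(axis=2)
        assert changed.any()
        bright = b[changed]
        assert bright.min(axis=1).mean() > 200          # high brightness
        sat = bright.max(axis=1) - bright.min(axis=1)
        assert sat.mean() < 20                          # low saturation


class TestRasterize:
    def test_square_polygon_matches_brute_force(self):
        # even-odd point-in-polygon oracle evaluated per pixel center
        poly = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], float)
        ann = AnnotatedImage(image=np.zeros((20, 20, 3), np.uint8),
                             cervix_box=Box(0, 0, 20, 20),
                             lesions=[(poly, "LSIL")])
        mask = rasterize_lesions(ann)
        oracle = np.zeros((20, 20), bool)
        for r in range(20):
            for c in range(20):
                oracle[r, c] = _point_in_polygon_evenodd(
                    c + 0.5, r + 0.5, poly)
        assert np.array_equal(mask, oracle)

    def test_random_simple_polygons_match_shapely(self):
        # independent oracle: shapely point containment on star-shaped
        # (hence simple) random polygons, off-boundary pixel centers only
        rng = np.random.default_rng(0)
        for _ in range(10):
            k = int(rng.integers(3, 10))
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            rad = rng.uniform(3, 13, k)
            poly = np.stack([15 + rad * np.cos(ang),
                             15 + rad * np.sin(ang)], axis=1)
            sh = Polygon(poly)
            assert sh.is_valid
            mask = polygon_mask(poly, 30, 30)
            for r in range(30):
                for c in range(30):
                    p = Point(c + 0.5, r + 0.5)
                    if sh.boundary.distance(p) > 1e-9:
                        assert mask[r, c] == sh.contains(p), (r, c)

    def test_label_filter_selects_single_blob(self, mixed_label_scene):
        ann = mixed_label_scene
        all_mask = rasterize_lesions(ann)
        h_mask = rasterize_lesions(ann, label_filter="HSIL+")
        l_mask = rasterize_lesions(ann, label_filter="LSIL")
        assert np.array_equal(all_mask, h_mask | l_mask)
        only_h = [polygon_mask(p, *all_mask.shape)
                  for p, lab in ann.lesions if lab == "HSIL+"]
        assert np.array_equal(h_mask, np.any(only_h, axis=0))

    def test_degenerate_polygon_raises(self):
        ann = AnnotatedImage(image=np.zeros((8, 8, 3), np.uint8),
                             cervix_box=Box(0, 0, 8, 8),
                             lesions=[(np.array([[1, 1], [2, 2]], float),
                                       "LSIL")])
        with pytest.raises(ValueError, match="3"):
            rasterize_lesions(ann)


def _point_in_polygon_evenodd(px, py, poly):
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 > py) != (y2 > py):
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xi:
                inside = not inside
    return inside


class TestLabelMe:
    def test_round_trip_preserves_annotations(self, small_scene, tmp_path):
        path = tmp_path / f"{small_scene.id}.json"
        write_labelme(small_scene, path)
        back = read_labelme(path)
        assert back.cervix_box == small_scene.cervix_box
        assert back.image.shape == small_scene.image.shape
        assert np.array_equal(back.image, small_scene.image)
        assert len(back.lesions) == len(small_scene.lesions)
        for (pa, la), (pb, lb) in zip(small_scene.lesions, back.lesions):
            assert la == lb
            np.testing.assert_allclose(pa, pb, atol=1e-6)

    def test_dialect_structure(self, small_scene, tmp_path):
        path = tmp_path / "scene.json"
        write_labelme(small_scene, path)
        doc = json.loads(path.read_text())
        for key in ("imagePath", "imageHeight", "imageWidth", "shapes"):
            assert key in doc
        types = {s["shape_type"] for s in doc["shapes"]}
        assert "rectangle" in types and "polygon" in types
        rect = next(s for s in doc["shapes"] if s["shape_type"] == "rectangle")
        assert len(rect["points"]) == 2

    def test_rectangle_as_polygon_accepted(self, small_scene, tmp_path):
        path = tmp_path / "scene.json"
        write_labelme(small_scene, path)
        doc = json.loads(path.read_text())
        b = small_scene.cervix_box
        for s in doc["shapes"]:
            if s["shape_type"] == "rectangle":
                s["shape_type"] = "polygon"
                s["points"] = [[b.x, b.y], [b.x + b.w, b.y],
                               [b.x + b.w, b.y + b.h], [b.x, b.y + b.h]]
        path.write_text(json.dumps(doc))
        assert read_labelme(path).cervix_box == b

    def test_missing_shapes_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"imagePath": "x.png", "imageHeight": 4,
                                    "imageWidth": 4}))
        with pytest.raises(LabelMeError, match="shapes"):
            read_labelme(path)

    def test_subpixel_precision_survives(self, tmp_path):
        poly = np.array([[1.123456, 2.654321], [5.000001, 2.1],
                         [3.5, 6.999999]])
        ann = AnnotatedImage(image=np.zeros((10, 10, 3), np.uint8),
                             cervix_box=Box(0, 0, 10, 10),
                             lesions=[(poly, "HSIL+")])
        path = tmp_path / "p.json"
        write_labelme(ann, path)
        back = read_labelme(path)
        np.testing.assert_allclose(back.lesions[0][0], poly, atol=1e-6)
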