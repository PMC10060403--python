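import math

import numpy as np
import pytest

from spotgrid.grid import (
    GridDetectionError,
    detect_grid,
    estimate_rotation,
    extract_rois,
    fit_grid,
    postprocess_elements,
    preprocess,
    segment_elements,
    semi_automated_grid,
)
from spotgrid.models import GridModel, fold_angle_deg
from spotgrid.synthetic import SceneSpec, generate_grid_scene


def lattice_points(rows, cols, pitch, rotation_deg, origin=(50.0, 50.0)):
    t = math.radians(rotation_deg)
    pts = []
    for i in range(rows):
        for j in range(cols):
            x = j * pitch * math.cos(t) - i * pitch * math.sin(t)
            y = j * pitch * math.sin(t) + i * pitch * math.cos(t)
            pts.append((origin[0] + x, origin[1] + y))
    return np.array(pts)


class TestPreprocess:
    def test_two_level_16bit(self):
        img = np.zeros((20, 20), dtype=np.uint16)
        img[5:15, 5:15] = 65535
        out = preprocess(img, 1, 99)
        assert set(np.unique(out)) == {0.0, 1.0}

    def test_rgb_equal_channels_matches_single(self):
        rng = np.random.default_rng(0)
        plane = rng.uniform(size=(16, 16))
        rgb = np.stack([plane, plane, plane])
        np.testing.assert_allclose(preprocess(rgb, 0, 100), preprocess(plane, 0, 100), atol=1e-12)

    def test_full_range_ramp(self):
        ramp = np.tile(np.arange(256, dtype=float), (4, 1))
        out = preprocess(ramp, 0, 100)
        np.testing.assert_allclose(out, ramp / 255.0, atol=1e-6)

    def test_constant_image_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess(np.full((8, 8), 3.0), 1, 99)
        assert out.sum() == 0.0

    def test_bad_percentiles(self):
        with pytest.raises(ValueError, match="percentile"):
            preprocess(np.zeros((4, 4)), 50, 10)


class TestSegmentElements:
    def test_otsu_recovers_planted_discs(self, clean_grid_scene):
        img = preprocess(clean_grid_scene.images["grid"], 0, 100)
        mask = segment_elements(img, "otsu")
        truth = clean_grid_scene.truth_instances["grid"] > 0
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        assert inter / union >= 0.99

    def test_all_background_empty(self):
        assert segment_elements(np.zeros((10, 10)), "otsu").sum() == 0

    def test_percentile_foreground_fraction(self, rng):
        img = rng.permutation(np.linspace(0, 1, 10000)).reshape(100, 100)
        mask = segment_elements(img, "percentile", q=90.0)
        assert abs(mask.mean() - 0.10) < 0.01

    def test_external_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            segment_elements(np.zeros((10, 10)), "external", scores=np.zeros((5, 5)))

    def test_external_scores_thresholded(self):
        scores = np.zeros((6, 6))
        scores[2:4, 2:4] = 0.9
        mask = segment_elements(np.zeros((6, 6)), "external", scores=scores)
        assert mask.sum() == 4


class TestPostprocess:
    def _disc_mask(self, shape, discs):
        m = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for cx, cy, r in discs:
            m |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        return m

    def test_specks_filtered(self):
        discs = [(20 + 40 * j, 20 + 40 * i, 10) for i in range(4) for j in range(6)]
        mask = self._disc_mask((160, 260), discs)
        rng = np.random.default_rng(1)
        for _ in range(5):
            mask[rng.integers(0, 160), rng.integers(0, 260)] = True
        out = postprocess_elements(mask, open_radius=1, area_band=(0.3, 3.0))
        assert len(out) == 24

    def test_single_component_survives(self):
        mask = self._disc_mask((40, 40), [(20, 20, 8)])
        out = postprocess_elements(mask, open_radius=0)
        assert len(out) == 1

    def test_merged_pair_removed(self):
        # 20 singles plus one double-area component from two merged discs
        discs = [(20 + 40 * j, 20 + 40 * i, 10) for i in range(4) for j in range(5)]
        mask = self._disc_mask((180, 260), discs)
        merged = self._disc_mask((180, 260), [(220, 20, 10), (238, 20, 10)])
        mask |= merged
        out = postprocess_elements(mask, open_radius=0, area_band=(0.3, 1.5))
        assert len(out) == 20


    def test_empty_mask_raises(self):
        with pytest.raises(GridDetectionError):
            postprocess_elements(np.zeros((10, 10), dtype=bool))


class TestEstimateRotation:
    def test_axis_aligned(self):
        pts = lattice_points(4, 6, 30, 0.0)
        assert abs(estimate_rotation(pts)) < 1e-9

    @pytest.mark.parametrize("angle", [5.0, -7.5, 20.0])
    def test_planted_rotation(self, angle):
        pts = lattice_points(5, 5, 30, angle)
        assert estimate_rotation(pts) == pytest.approx(angle, abs=0.2)

    def test_fold_ambiguity(self):
        pts = lattice_points(5, 5, 30, 93.0)
        assert estimate_rotation(pts) == pytest.approx(3.0, abs=0.2)

    def test_fold_property_square_lattice(self):
        a = estimate_rotation(lattice_points(4, 4, 30, 10.0))
        b = estimate_rotation(lattice_points(4, 4, 30, 100.0))
        assert a == pytest.approx(b, abs=1e-6)

    def test_too_few_centroids(self):
        with pytest.raises(GridDetectionError, match="2 centroids"):
            estimate_rotation(np.array([[0.0, 0.0]]))


class TestFitGrid:
    def test_noise_free_recovery(self):
        spec = SceneSpec(rows=4, cols=6, rotation_deg=0.0, noise_sigma=0.0)
        scene = generate_grid_scene(spec)
        g = detect_grid(scene.images["grid"])
        t = scene.truth_grid
        assert (g.rows, g.cols) == (4, 6)
        assert g.origin_x == pytest.approx(t.origin_x, abs=0.5)
        assert g.origin_y == pytest.approx(t.origin_y, abs=0.5)
        assert g.pitch_x == pytest.approx(t.pitch_x, rel=0.01)
        assert g.pitch_y == pytest.approx(t.pitch_y, rel=0.01)
        assert g.spot_radius == pytest.approx(t.spot_radius, rel=0.02)

    def test_missing_spot_with_expected_shape(self):
        spec = SceneSpec(rows=4, cols=6, noise_sigma=0.0)
        scene = generate_grid_scene(spec)
        img = scene.images["grid"].copy()
        # erase the interior spot at grid index (1, 2)
        cx, cy = scene.truth_grid.center(1, 2)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 15**2] = spec.background_level
        g = detect_grid(img, expected_shape=(4, 6))
        assert (g.rows, g.cols) == (4, 6)

    def test_irreconcilable_shape_rejected(self, clean_grid_scene):
        with pytest.raises(GridDetectionError, match="irreconcilable"):
            detect_grid(clean_grid_scene.images["grid"], expected_shape=(7, 9))

    def test_noisy_recovery_within_3_percent(self):
        spec = SceneSpec(rows=4, cols=6, rotation_deg=4.0, noise_sigma=0.05, seed=13)
        scene = generate_grid_scene(spec)
        g = detect_grid(scene.images["grid"])
        t = scene.truth_grid
        for f in ("origin_x", "origin_y", "pitch_x", "pitch_y", "spot_radius"):
            assert abs(getattr(g, f) - getattr(t, f)) / abs(getattr(t, f)) <= 0.03

    def test_too_few_elements(self):
        from spotgrid.grid import DetectedElementSet

        elems = DetectedElementSet(
            labels=np.zeros((4, 4), dtype=int),
            centroids=np.array([[0.0, 0.0], [10.0, 0.0]]),
            areas=np.array([5.0, 5.0]),
        )
        with pytest.raises(GridDetectionError, match="4 elements"):
            fit_grid(elems, 0.0)


class TestSemiAutomated:
    def test_two_corner_example(self):
        g = semi_automated_grid(
            known={"rows": 4, "cols": 6, "rotation_deg": 0.0, "spot_radius": 8.0},
            clicked_points=[(10, 10), (110, 70)],
        )
        assert g.pitch_x == pytest.approx(20.0)
        assert g.pitch_y == pytest.approx(20.0)
        assert (g.origin_x, g.origin_y) == (10.0, 10.0)

    def test_identity_passthrough(self):
        full = dict(rows=3, cols=3, origin_x=5.0, origin_y=6.0, pitch_x=20.0,
                    pitch_y=25.0, rotation_deg=2.0, spot_radius=7.0)
        g = semi_automated_grid(known=full)
        assert g.to_dict() == pytest.approx(full)

    def test_rotation_from_three_corners(self):
        truth = GridModel(rows=4, cols=6, origin_x=30.0, origin_y=40.0, pitch_x=20.0,
                          pitch_y=22.0, rotation_deg=5.0, spot_radius=6.0)
        pts = [truth.center(0, 0), truth.center(0, 5), truth.center(3, 0)]
        g = semi_automated_grid(
            known={"rows": 4, "cols": 6, "spot_radius": 6.0}, clicked_points=pts
        )
        assert g.rotation_deg == pytest.approx(5.0, abs=1e-6)
        assert g.pitch_x == pytest.approx(20.0, abs=1e-9)
        assert g.pitch_y == pytest.approx(22.0, abs=1e-9)

    def test_underdetermined_lists_missing(self):
        with pytest.raises(ValueError, match="missing.*spot_radius"):
            semi_automated_grid(known={"rows": 4, "cols": 6}, clicked_points=[(0, 0), (1, 1)])


class TestExtractRois:
    def test_count_and_order(self, clean_grid_scene):
        rois = extract_rois(clean_grid_scene.images["grid"], clean_grid_scene.truth_grid)
        assert len(rois) == 24
        assert rois[0].grid_index == (0, 0)
        assert rois[-1].grid_index == (3, 5)

    def test_disjoint_masks(self, clean_grid_scene):
        rois = extract_rois(clean_grid_scene.images["grid"], clean_grid_scene.truth_grid)
        h, w = clean_grid_scene.images["grid"].shape
        cover = np.zeros((h, w), dtype=int)
        for r in rois:
            x0, y0, x1, y1 = r.bbox
            cover[y0:y1, x0:x1] += r.mask
        assert cover.max() == 1

    def test_total_mask_area(self, clean_grid_scene):
        rois = extract_rois(clean_grid_scene.images["grid"], clean_grid_scene.truth_grid)
        total = sum(r.mask.sum() for r in rois)
        # independent enumeration oracle: lattice points within r of each centre
        oracle = 0
        h, w = clean_grid_scene.images["grid"].shape
        for cx, cy in clean_grid_scene.truth_grid.centers():
            oracle += sum(
                1
                for y in range(h)
                for x in range(w)
                if (x - cx) ** 2 + (y - cy) ** 2 <= 12**2
            )
        assert total == oracle
        # rasterization tracks the analytic disc area (Gauss-circle
        # fluctuation at integer centres reaches ~2.5% for r = 12)
        expected = 24 * math.pi * 12**2
        assert abs(total - expected) / expected < 0.03

    def test_center_outside_rejected(self):
        g = GridModel(rows=2, cols=2, origin_x=5, origin_y=5, pitch_x=50, pitch_y=50,
                      rotation_deg=0.0, spot_radius=4)
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            extract_rois(np.zeros((40, 40)), g)


class TestProperties:
    def test_rotation_equivariance(self):
        base, delta = 3.0, 7.0
        specs = [SceneSpec(rows=4, cols=6, rotation_deg=a, noise_sigma=0.02, seed=5)
                 for a in (base, base + delta)]
        fits = [detect_grid(generate_grid_scene(s).images["grid"]) for s in specs]
        assert fits[1].rotation_deg - fits[0].rotation_deg == pytest.approx(delta, abs=0.5)
        assert fits[1].pitch_x == pytest.approx(fits[0].pitch_x, rel=0.01)
        assert fits[1].spot_radius == pytest.approx(fits[0].spot_radius, rel=0.01)

    def test_pipeline_idempotence(self, clean_grid_scene):
        a = detect_grid(clean_grid_scene.images["grid"])
        b = detect_grid(clean_grid_scene.images["grid"])
        assert a.to_dict() == b.to_dict()

    def test_fold_angle_range(self):
        for a in np.linspace(-400, 400, 161):
            f = fold_angle_deg(a)
            assert -45.0 < f <= 45.0
            # folding is a congruence modulo 90
            assert abs((a - f) % 90.0) < 1e-9 or abs((a - f) % 90.0 - 90.0) < 1e-9
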