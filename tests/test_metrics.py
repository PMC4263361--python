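"""Plate detection, segmentation, and the P2A/BF shape statistics."""

import numpy as np
import pytest
from skimage import draw

from colonymorph import metrics, synthetic
from colonymorph.containers import Disc, PlateImage
from colonymorph.masks import ColonyMask, mask_perimeter
from colonymorph.metrics import (
    PlateNotFoundError,
    SegmentationError,
    area_timecourse,
    classify_convexity,
    compute_bf,
    compute_p2a,
    detect_plate,
    segment_colony,
)


def _disc_grid(radius, shape=None, center=None):
    shape = shape or (2 * radius + 40, 2 * radius + 40)
    center = center or (shape[0] // 2, shape[1] // 2)
    grid = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, radius)
    grid[rr, cc] = True
    return grid


class TestDetectPlate:
    def test_recovers_synthetic_plate_geometry(self):
        spec = synthetic.SceneSpec(
            shape=(640, 640), plate_radius=300.0,
            petals=synthetic.PetalSpec(150.0), noise_sd=5.0, seed=3)
        img, _ = synthetic.make_plate_scene(spec)
        plate = detect_plate(img)
        assert plate.radius == pytest.approx(300.0, abs=2.0)
        assert plate.center[0] == pytest.approx(spec.plate_center[0], abs=2.0)
        assert plate.center[1] == pytest.approx(spec.plate_center[1], abs=2.0)

    def test_constant_image_raises(self):
        with pytest.raises(PlateNotFoundError, match="no plate found"):
            detect_plate(PlateImage(np.full((100, 100), 7.0)))

    def test_disc_isolating_threshold_beats_merging_one(self):
        # a disc at intensity 100 with dimmer tendrils attached at 50:
        # thresholding at 75 isolates the disc, at 25 merges both
        arr = np.full((300, 300), 0.0)
        arr[_disc_grid(100, (300, 300), (150, 150))] = 100.0
        arr[148:152, 250:295] = 50.0
        arr[5:50, 148:152] = 50.0
        comp_iso = arr > 75
        comp_merged = arr > 25
        cost_iso = mask_perimeter(comp_iso) ** 2 / (4 * np.pi * comp_iso.sum())
        cost_merged = mask_perimeter(comp_merged) ** 2 / (4 * np.pi * comp_merged.sum())
        assert cost_iso < cost_merged  # brute-force comparison
        plate = detect_plate(PlateImage(arr), threshold_grid=[25.0, 75.0])
        assert plate.circularity_cost == pytest.approx(cost_iso, rel=1e-6)
        assert plate.radius == pytest.approx(100.0, abs=2.0)


class TestSegmentColony:
    def test_noiseless_scene_iou_above_095(self):
        spec = synthetic.SceneSpec(petals=synthetic.PetalSpec(100.0, harmonics=((5, 0.1, 0.0),)))
        img, _ = synthetic.make_plate_scene(spec)
        mask = segment_colony(img, detect_plate(img))
        truth = synthetic.colony_raster_truth(spec)
        iou = (mask.grid & truth).sum() / (mask.grid | truth).sum()
        assert iou > 0.95

    def test_uniform_interior_raises(self):
        arr = np.full((200, 200), 10.0)
        arr[_disc_grid(80, (200, 200))] = 60.0
        with pytest.raises(SegmentationError, match="unimodal"):
            segment_colony(PlateImage(arr), Disc(center=(100, 100), radius=80))

    def test_valley_threshold_between_engineered_modes(self):
        # histogram with modes at 40 and 200 and a unique engineered
        # valley at 110; brute-force scan is the oracle
        values = []
        for v in range(256):
            n = int(2000 * np.exp(-0.5 * ((v - 40) / 25) ** 2)
                    + 2000 * np.exp(-0.5 * ((v - 200) / 40) ** 2)) + 5
            if v == 110:
                n = 1
            values.append(np.full(n, float(v)))
        values = np.concatenate(values)
        threshold, method = metrics._histogram_threshold(values)
        assert method == "valley"
        assert 100 <= threshold <= 120


class TestComputeP2A:
    def test_analytic_circle_is_one(self):
        R = 50.0
        assert (2 * np.pi * R) ** 2 / (4 * np.pi * np.pi * R**2) == pytest.approx(1.0)

    def test_rasterized_disc_within_3pct(self, disc_mask):
        assert compute_p2a(disc_mask) == pytest.approx(1.0, rel=0.03)

    def test_square_closed_form(self):
        grid = np.zeros((160, 160), dtype=bool)
        grid[30:130, 30:130] = True
        assert compute_p2a(ColonyMask(grid)) == pytest.approx(4 / np.pi, rel=0.03)

    def test_disc_matches_polygon_oracle(self, disc_mask):
        truth = synthetic.boundary_ground_truth(synthetic.PetalSpec(100.0))
        assert compute_p2a(disc_mask) == pytest.approx(truth.p2a, rel=0.03)

    def test_pixel_count_mode_reproduces_literal_rule(self, disc_mask):
        literal = ColonyMask(disc_mask.grid, perimeter_mode="pixel-count")
        from colonymorph.masks import boundary_pixels

        assert literal.perimeter == boundary_pixels(disc_mask.grid).sum()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            compute_p2a(ColonyMask(np.zeros((10, 10), dtype=bool)))


class TestComputeBF:
    def test_circle_bf_near_zero(self):
        # digitization jitter of the traced boundary shrinks like 1/R;
        # at R = 150 the residual BF sits well below the 1e-3 anchor
        assert compute_bf(ColonyMask(_disc_grid(150))) < 1e-3

    def test_harmonic_boundary_closed_form(self):
        spec = synthetic.SceneSpec(petals=synthetic.PetalSpec(100.0, harmonics=((5, 0.1, 0.0),)))
        mask = ColonyMask(synthetic.colony_raster_truth(spec))
        assert compute_bf(mask) == pytest.approx(0.1 / np.sqrt(2), rel=0.05)

    def test_arbitrary_petals_match_continuous_oracle(self):
        spec = synthetic.SceneSpec(
            petals=synthetic.PetalSpec(90.0, harmonics=((3, 0.06, 1.0), (7, 0.04, 0.2))))
        _, truth = synthetic.make_plate_scene(spec)
        mask = ColonyMask(synthetic.colony_raster_truth(spec))
        assert compute_bf(mask) == pytest.approx(truth.bf, rel=0.05)

    def test_too_few_bins_rejected(self, disc_mask):
        with pytest.raises(ValueError, match="36"):
            compute_bf(disc_mask, n_angular_bins=10)

    def test_empty_angular_bin_names_the_bin(self):
        # a 1-pixel-wide bar leaves most angular bins without boundary pixels
        grid = np.zeros((50, 50), dtype=bool)
        grid[25, 5:45] = True
        with pytest.raises(ValueError, match=r"angular bin \d+"):
            compute_bf(ColonyMask(grid))


class TestShapeInvariances:
    def test_scale_invariance_within_2pct(self, disc_mask):
        big = ColonyMask(np.kron(disc_mask.grid, np.ones((2, 2), dtype=bool)))
        assert compute_p2a(big) == pytest.approx(compute_p2a(disc_mask), rel=0.02)
        assert compute_bf(big) == pytest.approx(compute_bf(disc_mask), abs=0.002)

    def test_rotation_invariance_exact(self):
        spec = synthetic.SceneSpec(petals=synthetic.PetalSpec(80.0, harmonics=((4, 0.1, 0.5),)))
        grid = synthetic.colony_raster_truth(spec)
        m0, m1 = ColonyMask(grid), ColonyMask(np.rot90(grid))
        assert compute_p2a(m1) == pytest.approx(compute_p2a(m0), rel=1e-9)
        assert compute_bf(m1) == pytest.approx(compute_bf(m0), rel=1e-9)

    def test_petal_strictly_increases_p2a_and_bf(self):
        plain = synthetic.SceneSpec(petals=synthetic.PetalSpec(90.0))
        petaled = synthetic.SceneSpec(petals=synthetic.PetalSpec(90.0, harmonics=((6, 0.12, 0.0),)))
        m_plain = ColonyMask(synthetic.colony_raster_truth(plain))
        m_petal = ColonyMask(synthetic.colony_raster_truth(petaled))
        assert compute_p2a(m_petal) > compute_p2a(m_plain)
        assert compute_bf(m_petal) > compute_bf(m_plain)


class TestTimecourse:
    def test_constant_masks_give_constant_series(self, disc_mask):
        df = area_timecourse([disc_mask] * 3)
        assert df["area"].nunique() == 1
        assert df["p2a"].nunique() == 1

    def test_growing_discs_increase_area_with_circular_shape(self):
        masks = [ColonyMask(_disc_grid(r, (220, 220))) for r in (40, 60, 80)]
        df = area_timecourse(masks)
        assert df["area"].is_monotonic_increasing
        assert np.allclose(df["p2a"], 1.0, atol=0.05)
        assert df.attrs["max_area"] == df["area"].iloc[-1]

    def test_single_frame_rejected(self, disc_mask):
        with pytest.raises(ValueError, match="2 frames"):
            area_timecourse([disc_mask])


class TestClassifyConvexity:
    def test_saturating_exponential_is_concave(self):
        df = synthetic.make_area_timecourse("concave")
        assert classify_convexity(df["t"], df["area"]) == "concave"

    def test_logistic_is_convex(self):
        df = synthetic.make_area_timecourse("convex")
        assert classify_convexity(df["t"], df["area"]) == "convex"

    def test_noisy_logistic_robust_over_seeds(self):
        hits = sum(
            classify_convexity(df["t"], df["area"]) == "convex"
            for df in (synthetic.make_area_timecourse("convex", noise_sd=0.01, seed=s)
                       for s in range(100))
        )
        assert hits >= 95

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="10 time points"):
            classify_convexity(np.arange(5), np.arange(5.0))
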