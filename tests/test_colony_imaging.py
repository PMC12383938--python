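"""Yen thresholding, connected-component counting, and per-well plate counts."""

import numpy as np
import pytest
from skimage.filters import threshold_yen as skimage_yen

import sobprbe as s
from conftest import brute_force_yen


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    h = np.zeros(256)
    n_bins = rng.integers(2, 40)
    bins = rng.choice(256, size=n_bins, replace=False)
    h[bins] = rng.integers(1, 1000, size=n_bins)
    return h


class TestYenThreshold:
    def test_two_spike_histogram_breaks_tie_at_lower_spike(self):
        h = np.zeros(256)
        h[50] = h[200] = 500
        # criterion is constant for t in [50, 199]; smallest t wins
        assert s.yen_threshold(h) == 50

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            h = random_histogram(rng)
            assert s.yen_threshold(h) == brute_force_yen(h)

    def test_matches_skimage_on_random_images(self):
        # independent implementation cross-check; allow one bin of slack for
        # float-accumulation near-ties on flat histograms
        rng = np.random.default_rng(7)
        for _ in range(20):
            img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
            h = np.bincount(img.ravel(), minlength=256)
            assert abs(s.yen_threshold(h) - int(skimage_yen(hist=(h, np.arange(256))))) <= 1

    def test_single_intensity_raises_uniform_image_error(self):
        h = np.zeros(256)
        h[128] = 1000
        with pytest.raises(s.UniformImageError):
            s.yen_threshold(h)

    def test_wrong_bin_count_rejected(self):
        with pytest.raises(ValueError):
            s.yen_threshold(np.ones(100))


class TestCountColoniesInMask:
    def test_empty_mask_counts_zero(self):
        n, labels = s.count_colonies_in_mask(np.zeros((20, 20), bool))
        assert n == 0 and labels.max() == 0

    def test_four_pixel_object_filtered_five_pixel_object_kept(self):
        mask = np.zeros((10, 20), bool)
        mask[2, 2:6] = True      # 4 px: below the "bigger than four pixels" cut
        mask[6, 10:15] = True    # 5 px: counted
        n, labels = s.count_colonies_in_mask(mask)
        assert n == 1
        assert set(np.unique(labels)) - {0} == {2}

    def test_connectivity_four_splits_diagonal_chain(self):
        mask = np.zeros((12, 12), bool)
        for i in range(5):  # 5-px diagonal: one component at 8-conn, five at 4-conn
            mask[i, i] = True
        n8, _ = s.count_colonies_in_mask(mask, s.ImagingConfig(connectivity=8))
        n4, _ = s.count_colonies_in_mask(
            mask, s.ImagingConfig(connectivity=4, min_colony_area_px=1)
        )
        assert n8 == 1
        assert n4 == 5

    def test_twelve_rendered_disks_count_twelve(self):
        scene = s.ImageScene(wells=((0, 0, 12),), n_rows=1, n_cols=1,
                             well_pitch_px=96, roi_radius_px=44.0)
        img, _ = s.render_plate_image(scene, seed=3)
        mask = img < 150
        n, _ = s.count_colonies_in_mask(mask)
        assert n == 12


class TestCountPlate:
    @pytest.fixture()
    def scene_and_rois(self):
        rng = np.random.default_rng(17)
        wells = tuple(
            (r, c, int(rng.integers(0, 7))) for r in range(4) for c in range(6)
        )
        scene = s.ImageScene(wells=wells, n_rows=4, n_cols=6)
        rois = s.grid_rois(4, 6, 48.0, 20.0)
        return scene, rois

    def test_background_only_plate_counts_zero_everywhere(self):
        scene = s.ImageScene(
            wells=tuple((r, c, 0) for r in range(4) for c in range(6)),
            n_rows=4, n_cols=6, noise_sd=1.5,
        )
        img, _ = s.render_plate_image(scene, seed=21)
        table = s.count_plate(img, s.grid_rois(4, 6, 48.0, 20.0))
        assert (table["colony_count"] == 0).all()

    def test_exact_recovery_of_known_counts(self, scene_and_rois):
        scene, rois = scene_and_rois
        img, truth = s.render_plate_image(scene, seed=4)
        table = s.count_plate(img, rois)
        merged = truth.merge(table, on=["row", "col"], suffixes=("_true", "_meas"))
        assert (merged["colony_count_true"] == merged["colony_count_meas"]).all()

    def test_counting_is_deterministic(self, scene_and_rois):
        scene, rois = scene_and_rois
        img, _ = s.render_plate_image(scene, seed=4)
        t1 = s.count_plate(img, rois)
        t2 = s.count_plate(img, rois)
        assert t1.equals(t2)

    def test_adding_a_disk_increments_count_by_one(self):
        base = s.ImageScene(wells=((0, 0, 3),), n_rows=1, n_cols=1)
        more = s.ImageScene(wells=((0, 0, 4),), n_rows=1, n_cols=1)
        rois = s.grid_rois(1, 1, 48.0, 20.0)
        n3 = s.count_plate(s.render_plate_image(base, seed=8)[0], rois)
        n4 = s.count_plate(s.render_plate_image(more, seed=8)[0], rois)
        assert n4.loc[0, "colony_count"] == n3.loc[0, "colony_count"] + 1

    def test_counts_invariant_to_contrast_rescaling(self, scene_and_rois):
        """Order-preserving affine intensity maps leave colony counts unchanged."""
        scene, rois = scene_and_rois
        img, _ = s.render_plate_image(scene, seed=4)
        rescaled = np.round(img.astype(float) * 0.5 + 20).astype(np.uint8)
        t1 = s.count_plate(img, rois)
        t2 = s.count_plate(rescaled, rois)
        assert (t1["colony_count"] == t2["colony_count"]).all()

    def test_roi_outside_image_raises(self):
        img = np.full((96, 96), 200, np.uint8)
        bad = [s.WellROI(0, 0, 90.0, 90.0, 20.0)]
        with pytest.raises(s.ROIError):
            s.count_plate(img, bad)

    def test_overlapping_rois_raise(self):
        img = np.full((96, 96), 200, np.uint8)
        bad = [s.WellROI(0, 0, 40.0, 40.0, 20.0), s.WellROI(0, 1, 40.0, 60.0, 20.0)]
        with pytest.raises(s.ROIError):
            s.count_plate(img, bad)

    def test_non_uint8_image_rejected(self):
        img = np.zeros((96, 96), np.uint16)
        with pytest.raises(ValueError):
            s.count_plate(img, s.grid_rois(1, 1, 48.0, 20.0))

    def test_whole_plate_threshold_mode(self, scene_and_rois):
        scene, rois = scene_and_rois
        img, truth = s.render_plate_image(scene, seed=4)
        cfg = s.ImagingConfig(per_well_threshold=False)
        table = s.count_plate(img, rois, cfg)
        merged = truth.merge(table, on=["row", "col"], suffixes=("_true", "_meas"))
        assert (merged["colony_count_true"] == merged["colony_count_meas"]).all()
        assert table["threshold_used"].nunique() == 1
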