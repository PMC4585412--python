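"""Synthetic scan generator: determinism, placement, truth bookkeeping."""

import numpy as np
import pytest

from leafscore.calibration import DEFAULT_PROFILE
from leafscore.errors import CapacityError
from leafscore.segmentation import DEFAULT_BANDS, band_mask, rgb_to_hsl8
from leafscore.synthetic import (
    CLASS_CODES,
    LeafSpec,
    leaf_local_mask,
    render_scan,
    sample_plant,
    split_frames,
)

MPP = DEFAULT_PROFILE.mm_per_pixel

SMALL = dict(
    length_range_mm=(25.0, 60.0),
    width_range_mm=(5.0, 9.0),
    canvas_cols=320,
    dust_density=5.0,
)


class TestSamplePlant:
    def test_single_leaf_truth(self):
        task = sample_plant(1, {"green-3": 1.0}, seed=7, **SMALL)
        assert task.truth.LN == 1

    def test_same_seed_identical(self, cfg):
        a = sample_plant(5, seed=1, **SMALL)
        b = sample_plant(5, seed=1, **SMALL)
        assert a.leaves == b.leaves
        ra = render_scan(a, cfg.calibration)
        rb = render_scan(b, cfg.calibration)
        assert (ra.rgb == rb.rgb).all()

    def test_leaves_do_not_overlap(self, cfg):
        task = sample_plant(40, seed=5, **SMALL)
        scan = render_scan(task, cfg.calibration)
        # every foreground pixel carries exactly one leaf id, so the sum of
        # individual leaf masks must equal the labelled foreground
        total_px = sum(
            leaf_local_mask(leaf, MPP).sum() for leaf in task.leaves
        )
        assert (scan.leaf_labels > 0).sum() == total_px

    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sample_plant(3, {"green-2": 0.5}, seed=0, **SMALL)

    def test_canvas_too_narrow_raises(self):
        with pytest.raises(CapacityError):
            sample_plant(1, seed=0, length_range_mm=(100, 101),
                         width_range_mm=(50, 51), canvas_cols=100)

    def test_colour_centres_strictly_inside_their_band(self):
        task = sample_plant(20, seed=9, **SMALL)
        for leaf in task.leaves:
            band = DEFAULT_BANDS.band_for(leaf.colour_class)
            assert band.contains(*leaf.hsl_centre)


class TestRenderScan:
    def test_background_outside_all_bands(self, cfg):
        task = sample_plant(2, seed=1, **SMALL)
        scan = render_scan(task, cfg.calibration)
        hsl = rgb_to_hsl8(scan.rgb)
        bg = scan.leaf_labels == 0
        fg_band = band_mask(hsl, DEFAULT_BANDS.green) | band_mask(
            hsl, DEFAULT_BANDS.yellow
        )
        # background pixels in a leaf band can only be dust specks (<21 px each)
        assert (fg_band & bg).sum() < 21 * 40

    def test_leaf_band_mask_equals_truth_labels(self, cfg):
        task = sample_plant(
            3, {"green-3": 1.0}, seed=2, dust_density=0.0,
            length_range_mm=(25, 60), width_range_mm=(5, 9), canvas_cols=320,
        )
        scan = render_scan(task, cfg.calibration)
        hsl = rgb_to_hsl8(scan.rgb)
        assert (
            band_mask(hsl, DEFAULT_BANDS.green3) == (scan.leaf_labels > 0)
        ).all()

    def test_rectangle_pixel_count_matches_analytic_rasterisation(self, cfg):
        spec = LeafSpec(100.0, 10.0, "rectangle", 0.0, "green-3", (85, 150, 130), (10, 10))
        mask = leaf_local_mask(spec, MPP)
        assert mask.sum() == round(100 / MPP) * round(10 / MPP)

    def test_rasterisation_area_within_two_percent(self):
        rng = np.random.default_rng(0)
        for shape in ("rectangle", "tapered-ellipse", "curved-blade"):
            for _ in range(5):
                length = float(rng.uniform(20, 120))
                width = float(rng.uniform(4, 15))
                curv = float(rng.uniform(0.3, 0.9)) if shape == "curved-blade" else 0.0
                spec = LeafSpec(length, min(width, 0.8 * length), shape, curv,
                                "green-3", (85, 150, 130), (0, 0))
                raster_area = leaf_local_mask(spec, MPP).sum() * MPP**2
                assert raster_area == pytest.approx(spec.area_mm2, rel=0.02)

    def test_dust_specks_below_impurity_threshold(self, cfg):
        from skimage import measure as skmeasure

        task = sample_plant(2, seed=4, **{**SMALL, "dust_density": 80.0})
        scan = render_scan(task, cfg.calibration)
        dust = (scan.rgb.sum(axis=-1) > 0) & (scan.leaf_labels == 0)
        labels = skmeasure.label(dust, connectivity=2)
        if labels.max():
            sizes = np.bincount(labels.ravel())[1:]
            assert sizes.max() < 50

    def test_truth_class_areas_sum_to_total(self):
        task = sample_plant(10, seed=6, **SMALL)
        t = task.truth
        assert t.GLA + sum(
            r.yellow_area_mm2 for r in task.truth_records()
        ) == pytest.approx(t.TLA)


class TestSplitFrames:
    def test_single_frame_when_raster_fits(self):
        raster = np.zeros((3000, 8, 3), dtype=np.uint8)
        assert len(split_frames(raster, 3000)) == 1

    def test_concatenation_identity(self):
        rng = np.random.default_rng(1)
        raster = rng.integers(0, 256, (9000, 8, 3), dtype=np.uint8)
        frames = split_frames(raster, 3000)
        assert len(frames) == 3
        assert (np.concatenate([f.pixels for f in frames]) == raster).all()

    def test_last_frame_may_be_shorter(self):
        raster = np.zeros((3500, 8, 3), dtype=np.uint8)
        frames = split_frames(raster, 3000)
        assert [f.height for f in frames] == [3000, 500]

    def test_boundary_crossing_leaf_appears_in_two_frames(self, cfg):
        task = sample_plant(6, seed=8, frame_height_px=400, **SMALL)
        scan = render_scan(task, cfg.calibration)
        frames = split_frames(scan.leaf_labels[..., None].repeat(3, -1), 400)
        assert len(frames) >= 2
        crossing = [
            leaf_id
            for leaf_id in range(1, len(task.leaves) + 1)
            if sum((f.pixels[..., 0] == leaf_id).any() for f in frames) >= 2
        ]
        assert crossing, "the generator must place at least one boundary-crossing leaf"

    def test_class_codes_cover_all_leaves(self, cfg):
        task = sample_plant(8, seed=10, **SMALL)
        scan = render_scan(task, cfg.calibration)
        for i, leaf in enumerate(task.leaves, start=1):
            codes = np.unique(scan.class_labels[scan.leaf_labels == i])
            assert codes.tolist() == [CLASS_CODES[leaf.colour_class]]
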