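"""Segmentation: thresholding, labeling, hole analysis, circularity, detection."""

from math import pi, sqrt

import numpy as np
import pytest

from endopos.segmentation import (
    SegmentationError,
    SegmentationParams,
    chain_code_perimeter,
    circularity,
    circularity_from_geometry,
    decompose_grapes,
    detect_endosomes,
    euler_number,
    fill_rings,
    filter_circularity,
    label8,
    segment_cell,
    segment_nucleus,
    split_merged_objects,
    threshold_mask,
)
from endopos.synthetic import render_cell

from .conftest import flood_fill_count, small_scene_spec, two_hole_grape_mask


def grid(values):
    """Pad a small array into a valid >=16x16 grid (top-left corner)."""
    values = np.asarray(values, dtype=float)
    out = np.zeros((max(16, values.shape[0]), max(16, values.shape[1])))
    out[: values.shape[0], : values.shape[1]] = values
    return out


class TestThresholdMask:
    def test_all_zero_grid_gives_empty_mask(self):
        assert not threshold_mask(np.zeros((16, 16)), 2.0).any()

    def test_hand_computed_positive_pixel_statistic(self):
        # positives {10,10,10,20}: mean 12.5, population SD ~ 4.33; at n=0
        # only the 20 exceeds T=12.5
        g = np.zeros((16, 16))
        g[0, :3] = 10
        g[0, 3] = 20
        mask = threshold_mask(g, 0.0)
        assert mask.sum() == 1 and mask[0, 3]
        # n=10 puts T far above the maximum
        assert not threshold_mask(g, 10.0).any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_n_sigma(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 255, (32, 32))
        previous = threshold_mask(g, 0.0)
        for n in (0.5, 1.0, 2.0, 4.0):
            current = threshold_mask(g, n)
            assert not (current & ~previous).any()  # mask(n2) subset of mask(n1)
            previous = current


class TestLabel8:
    def test_diagonal_pixels_join(self):
        m = np.zeros((16, 16), bool)
        m[3, 3] = m[4, 4] = True
        assert label8(m).n_objects == 1

    def test_empty_mask(self):
        objs = label8(np.zeros((16, 16), bool))
        assert objs.n_objects == 0 and objs.label_grid.max() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_masks_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(size=(16, 16)) < 0.4
        assert label8(m).n_objects == flood_fill_count(m, connectivity=8)

    def test_labels_in_raster_order_and_consistent(self):
        m = np.zeros((16, 16), bool)
        m[10, 1] = True   # later raster position
        m[2, 12] = True   # earlier raster position
        objs = label8(m)
        assert objs.label_grid[2, 12] == 1 and objs.label_grid[10, 1] == 2
        for k, coords in enumerate(objs.objects):
            assert (objs.label_grid[coords[:, 0], coords[:, 1]] == k + 1).all()


class TestSegmentNucleus:
    def test_clean_disc_centroid_within_half_pixel(self):
        image, truth = render_cell(small_scene_spec(seed=5, noise_sigma=0.0))
        nucleus = segment_nucleus(image.nucleus, SegmentationParams())
        err = np.hypot(
            nucleus.centroid[0] - truth.nucleus_center[0],
            nucleus.centroid[1] - truth.nucleus_center[1],
        )
        assert err <= 0.5

    def test_speck_discarded_largest_kept(self):
        # n_sigma=1 keeps the threshold between the dim positives and the disc
        g = np.zeros((32, 32))
        rr, cc = np.mgrid[0:32, 0:32]
        disc = np.hypot(rr - 16, cc - 16) <= 6
        g[disc] = 200.0
        g[2, 2] = g[2, 3] = 200.0  # 2-px speck
        g[24:31, 0:32] = 10.0      # dim positives so the threshold lands low
        nucleus = segment_nucleus(
            g, SegmentationParams(closing_radius_px=0, n_sigma_nucleus=1.0)
        )
        assert nucleus.mask.sum() == disc.sum()
        assert nucleus.centroid == pytest.approx((16.0, 16.0), abs=1e-9)

    def test_equal_area_tie_keeps_first_in_raster_order(self):
        g = np.zeros((32, 32))
        g[2:4, 2:4] = 200.0    # first in raster order
        g[20:22, 20:22] = 200.0
        g[28:31, 0:32] = 10.0  # dim positives keep T below 200
        nucleus = segment_nucleus(
            g, SegmentationParams(closing_radius_px=0, n_sigma_nucleus=1.0)
        )
        assert nucleus.centroid == pytest.approx((2.5, 2.5))

    def test_empty_mask_raises(self):
        with pytest.raises(SegmentationError, match="no nucleus"):
            segment_nucleus(np.zeros((16, 16)), SegmentationParams())


class TestSegmentCell:
    def test_filled_ellipse_area_is_exact(self):
        rr, cc = np.mgrid[0:64, 0:64]
        ellipse = ((rr - 32) / 20.0) ** 2 + ((cc - 32) / 12.0) ** 2 <= 1
        ee = np.where(ellipse, 50.0, 0.0)
        cell = segment_cell(ee, ee, SegmentationParams(closing_radius_px=0),
                            pixel_size=1000.0)
        assert cell.area_um2 == pytest.approx(float(ellipse.sum()))

    def test_interior_pocket_is_filled(self):
        rr, cc = np.mgrid[0:64, 0:64]
        ellipse = ((rr - 32) / 20.0) ** 2 + ((cc - 32) / 12.0) ** 2 <= 1
        pocket = (np.hypot(rr - 32, cc - 32) <= 4)
        ee = np.where(ellipse & ~pocket, 50.0, 0.0)
        cell = segment_cell(ee, None, SegmentationParams(closing_radius_px=0),
                            pixel_size=1000.0)
        assert cell.mask[32, 32]  # pocket now foreground
        assert cell.area_um2 == pytest.approx(float(ellipse.sum()))

    def test_generator_footprint_within_five_percent(self, small_scene,
                                                     default_params):
        image, truth = small_scene
        cell = segment_cell(image.ee, image.le, default_params)
        true_um2 = truth.cell_area_px * (image.pixel_size / 1000.0) ** 2
        assert cell.area_um2 == pytest.approx(true_um2, rel=0.05)

    def test_all_zero_raises(self):
        with pytest.raises(SegmentationError, match="no cell"):
            segment_cell(np.zeros((16, 16)), None, SegmentationParams(),
                         pixel_size=90.0)


class TestFillRings:
    def test_hand_counted_ring_becomes_solid(self):
        # 4x4 square ring (12 px) around a 2x2 hole (4 px) -> 16 px solid
        m = np.zeros((16, 16), bool)
        m[2:6, 2:6] = True
        m[3:5, 3:5] = False
        objs = fill_rings(label8(m), s_min=3)
        assert objs.n_objects == 1
        assert len(objs.objects[0]) == 16

    def test_solid_square_unchanged(self):
        m = np.zeros((16, 16), bool)
        m[2:6, 2:6] = True
        objs = fill_rings(label8(m), s_min=3)
        assert objs.n_objects == 1 and len(objs.objects[0]) == 16

    @pytest.mark.parametrize("area,survives", [(2, False), (3, True), (4, True)])
    def test_size_filter_is_exact_at_s_min(self, area, survives):
        m = np.zeros((16, 16), bool)
        m[0, :area] = True
        objs = fill_rings(label8(m), s_min=3)
        assert objs.n_objects == (1 if survives else 0)

    def test_max_hole_area_preserves_large_holes(self):
        mask, large, small = two_hole_grape_mask()
        objs = fill_rings(label8(mask), s_min=3, max_hole_area=10)
        # small hole filled, large hole survives: Euler = 1 - 1 = 0
        assert euler_number(objs) == 0


class TestEulerNumber:
    def test_disc_ring_and_two_holes(self):
        rr, cc = np.mgrid[0:32, 0:32]
        disc = np.hypot(rr - 16, cc - 16) <= 6
        assert euler_number(disc) == 1
        ring = disc & (np.hypot(rr - 16, cc - 16) > 3)
        assert euler_number(ring) == 0
        mask, _, _ = two_hole_grape_mask()
        assert euler_number(mask) == -1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_hole_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(size=(12, 12)) < 0.5
        n_obj = flood_fill_count(m, connectivity=8)
        # enclosed holes: 4-connected background regions not reaching border
        padded = np.pad(~m, 1, constant_values=True)
        n_bg = flood_fill_count(padded, connectivity=4)
        n_holes = n_bg - 1  # one background region touches the border frame
        assert euler_number(m) == n_obj - n_holes


class TestDecomposeGrapes:
    def test_small_hole_filled_into_body(self):
        m = np.zeros((16, 16), bool)
        m[2:7, 2:7] = True
        m[4, 4] = False  # 1-px hole < s_min
        objs = decompose_grapes(label8(m), s_min=10)
        assert objs.n_objects == 1
        assert len(objs.objects[0]) == 25  # hole absorbed

    def test_large_hole_extracted_remainder_discarded(self):
        mask, large, small = two_hole_grape_mask()
        objs = decompose_grapes(label8(mask), s_min=10)
        assert objs.n_objects == 1
        final = objs.mask_of(0)
        # the final object is solid and contains the former 15-px hole
        assert euler_number(final) == 1
        hole = np.zeros_like(mask)
        hole[6:9, 5:10] = True
        assert (final & hole).sum() == large

    def test_solid_blob_passes_through(self):
        m = np.zeros((16, 16), bool)
        m[3:8, 3:8] = True
        objs = decompose_grapes(label8(m), s_min=10)
        assert objs.n_objects == 1 and len(objs.objects[0]) == 25


class TestCircularity:
    def test_analytic_circle_is_exactly_one(self):
        for r in (0.5, 1.0, 7.3, 120.0):
            assert circularity_from_geometry(2 * pi * r, pi * r * r) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_analytic_square_closed_form(self):
        for L in (1.0, 5.0):
            c = circularity_from_geometry(4 * L, L * L)
            assert c == pytest.approx(4 / pi, abs=1e-12)

    def test_literal_four_a_variant_differs_by_pi(self):
        c = circularity_from_geometry(2 * pi, pi, four_a=True)
        assert c == pytest.approx(pi, abs=1e-12)

    def test_digitized_disc_within_pre_fixed_band(self):
        rr, cc = np.mgrid[0:41, 0:41]
        disc = (rr - 20.0) ** 2 + (cc - 20.0) ** 2 <= 100.0
        assert 0.8 <= circularity(disc) <= 1.2

    def test_digitized_disc_circularity_converges_and_stays_in_band(self):
        # the chain-code perimeter of a digitized circle converges to a small
        # constant overestimate, so c(r) converges (shrinking increments) and
        # must stay inside the published [0.6, 1.5] acceptance band
        values = []
        for r in (5, 10, 20, 40):
            size = 2 * r + 21
            rr, cc = np.mgrid[0:size, 0:size]
            disc = (rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= r * r
            values.append(circularity(disc))
        increments = np.abs(np.diff(values))
        assert (np.diff(increments) < 0).all()  # convergent sequence
        assert all(0.6 <= v <= 1.5 for v in values)

    def test_chain_code_perimeter_of_rectangle(self):
        m = np.zeros((16, 16), bool)
        m[2:6, 2:10] = True  # 4x8 rectangle: boundary chain 2*(3+7) = 20
        assert chain_code_perimeter(m) == pytest.approx(20.0)

    def test_degenerate_tiny_objects(self):
        m = np.zeros((16, 16), bool)
        m[3, 3] = True
        assert chain_code_perimeter(m) == pytest.approx(4.0)
        m[3, 4] = True
        assert chain_code_perimeter(m) == pytest.approx(6.0)

    def test_filter_inclusive_bounds(self):
        from endopos.segmentation import EndosomeObject

        def obj(c):
            return EndosomeObject(1, np.array([[0, 0]]), 1, 1.0, (0, 0), c, "LE")

        kept = filter_circularity(
            [obj(0.6), obj(1.0), obj(1.5), obj(0.59), obj(1.51)], (0.6, 1.5)
        )
        assert [o.circularity for o in kept] == [0.6, 1.0, 1.5]
        assert filter_circularity([], (0.6, 1.5)) == []

    def test_shape_triage_circle_square_rectangle(self):
        # closed-form c: circle 1, square 4/pi ~ 1.273, 10:1 rectangle ~ 3.85
        shapes = {
            "circle": circularity_from_geometry(2 * pi, pi),
            "square": circularity_from_geometry(4.0, 1.0),
            "bar": circularity_from_geometry(22.0, 10.0),
        }
        kept = {k for k, c in shapes.items() if 0.6 <= c <= 1.5}
        assert kept == {"circle", "square"}


class TestSplitMerged:
    def test_merged_pair_splits_lone_spot_does_not(self):
        m = np.zeros((40, 40), bool)
        rr, cc = np.mgrid[0:40, 0:40]
        m |= np.hypot(rr - 20, cc - 12) <= 3
        m |= np.hypot(rr - 20, cc - 19) <= 3  # fused pair
        m |= np.hypot(rr - 8, cc - 30) <= 1.5  # small lone spot sets the median
        m |= np.hypot(rr - 30, cc - 30) <= 1.5
        m |= np.hypot(rr - 33, cc - 8) <= 1.5
        objs = split_merged_objects(label8(m))
        assert objs.n_objects == 5  # pair split into two


class TestDetectEndosomes:
    def test_two_pixel_speck_removed(self):
        g = np.zeros((32, 32))
        g[10, 10:12] = 200.0
        g[20, 0:10] = 1.0  # dim positives keep the threshold below 200
        from endopos.segmentation import NucleusSegment

        nucleus = NucleusSegment(np.zeros((32, 32), bool), (0.0, 0.0))
        objs = detect_endosomes(g, "EE", nucleus, SegmentationParams(),
                                pixel_size=90.0)
        assert objs == []

    def test_recovery_on_small_scene(self, small_scene, calibrated_params):
        image, truth = small_scene
        nucleus = segment_nucleus(image.nucleus, calibrated_params)
        objs = detect_endosomes(image.ee, "EE", nucleus, calibrated_params)
        true_centers = np.array(
            [s.center for s in truth.spots if s.channel == "EE"]
        )
        assert len(objs) == pytest.approx(len(true_centers), abs=2)
        found = np.array([o.centroid for o in objs])
        errors = [np.hypot(*(found - t).T).min() for t in true_centers]
        errors = [e for e in errors if e <= 3.0]
        assert np.sqrt(np.mean(np.square(errors))) <= 1.0

    def test_output_never_overlaps_nucleus_and_respects_s_min(
        self, small_scene, calibrated_params
    ):
        image, truth = small_scene
        nucleus = segment_nucleus(image.nucleus, calibrated_params)
        for kind, channel in (("EE", image.ee), ("LE", image.le)):
            objs = detect_endosomes(channel, kind, nucleus, calibrated_params)
            s_min = calibrated_params.s_min(kind)
            for o in objs:
                assert o.area_px >= s_min
                assert not nucleus.mask[o.pixels[:, 0], o.pixels[:, 1]].any()

    def test_grape_fixture_through_channel(self):
        from endopos.segmentation import NucleusSegment

        mask, _, _ = two_hole_grape_mask()
        g = np.zeros((32, 32))
        g[:20, :24][mask] = 200.0
        g[30, 0:15] = 1.0  # dim positives: T = mean(positives) < 200 at n=0
        nucleus = NucleusSegment(np.zeros((32, 32), bool), (0.0, 0.0))
        params = SegmentationParams(n_sigma_endosome=0.0)
        objs = detect_endosomes(g, "LE", nucleus, params, pixel_size=90.0)
        assert len(objs) == 1
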