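import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.color import hsv2rgb

from artefactscan.crystals import (
    ColourClassSpec,
    Crystal,
    TileMosaic,
    classify_colours,
    dedup_overlap,
    default_colour_specs,
    density,
    detect_crystals,
    distance_histogram,
    pair_distances,
)
from artefactscan.errors import (
    GeometryError,
    InsufficientDataError,
    LowContrastWarning,
)


def rgb_pixel(hue_deg, sat=0.8, val=0.9):
    rgb = hsv2rgb(np.array([[[hue_deg / 360.0, sat, val]]]))
    return np.floor(rgb * 255 + 0.5).astype(np.uint8)


def fill_image(hue_deg, shape=(8, 8), sat=0.8, val=0.9):
    return np.tile(rgb_pixel(hue_deg, sat, val), (*shape, 1))


def make_crystal(x, y, colour="blue", tile=None):
    return Crystal(centroid_um=(x, y), colour=colour, area_um2=1.0, tile=tile)


class TestClassifyColours:
    def test_pure_blue_only_blue_mask(self):
        masks = classify_colours(fill_image(240.0))
        assert masks["blue"].all()
        assert not masks["red"].any()
        assert not masks["yellow"].any()

    def test_red_wraparound_hue(self):
        masks = classify_colours(fill_image(355.0))
        assert masks["red"].all()
        assert not masks["blue"].any()

    def test_dark_pixel_gated_out(self):
        with pytest.warns(LowContrastWarning):
            masks = classify_colours(fill_image(240.0, val=0.1))
        assert not any(m.any() for m in masks.values())

    def test_masks_mutually_exclusive(self):
        specs = [
            ColourClassSpec("wide", ((0.0, 360.0),), sat_min=0.0, val_min=0.0),
            ColourClassSpec("also_wide", ((0.0, 360.0),), sat_min=0.0, val_min=0.0),
        ]
        masks = classify_colours(fill_image(120.0), specs)
        assert masks["wide"].all()
        assert not masks["also_wide"].any()

    def test_grayscale_input_rejected(self):
        with pytest.raises(ValueError):
            classify_colours(np.zeros((4, 4), dtype=np.uint8))

    def test_low_coverage_warning(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)  # black: nothing matches
        with pytest.warns(LowContrastWarning, match="yellow"):
            classify_colours(img)


class TestDetectCrystals:
    def test_square_centroid_and_area(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 5:7] = True  # 4-px square, centroid at (2.5, 5.5) px
        found = detect_crystals(mask, min_area_px=1, scale=2.0, colour="blue")
        assert len(found) == 1
        c = found[0]
        assert c.centroid_um == pytest.approx((5.5 / 2.0, 2.5 / 2.0))
        assert c.area_um2 == pytest.approx(1.0)
        assert c.colour == "blue"

    def test_two_separated_components(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        assert len(detect_crystals(mask, min_area_px=1)) == 2

    def test_min_area_filter(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True  # 1 px speck
        mask[5:8, 5:8] = True  # 9 px blob
        found = detect_crystals(mask, min_area_px=4)
        assert len(found) == 1
        assert found[0].area_um2 == pytest.approx(9.0)

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = mask[3, 3] = True
        assert len(detect_crystals(mask, min_area_px=1)) == 1

    def test_empty_mask(self):
        assert detect_crystals(np.zeros((5, 5), dtype=bool)) == []


class TestMosaicGeometry:
    def test_step_from_overlap(self):
        mosaic = TileMosaic((2, 3), (100, 200), scale=2.0, overlap_frac=(0.2, 0.1))
        assert mosaic.tile_extent_um == (50.0, 100.0)
        assert mosaic.step == (40.0, 90.0)
        assert mosaic.tile_origin_um(1, 2) == (180.0, 40.0)

    def test_inconsistent_step_rejected(self):
        with pytest.raises(GeometryError):
            TileMosaic(
                (2, 2), (100, 100), scale=2.0, overlap_frac=(0.2, 0.2),
                step_um=(45.0, 45.0),
            )

    def test_bad_overlap_rejected(self):
        with pytest.raises(GeometryError):
            TileMosaic((1, 1), (10, 10), scale=1.0, overlap_frac=(1.0, 0.0))


class TestDedupOverlap:
    def mosaic(self, overlap=0.2):
        # 2 tiles side by side, 100x100 px at 1 px/um -> strip 20 um wide
        return TileMosaic((1, 2), (100, 100), scale=1.0, overlap_frac=(0.0, overlap))

    def test_shared_crystal_kept_once(self):
        mosaic = self.mosaic()
        # global x=85: local 85 in tile 0, local 5 (in-strip) in tile 1
        per_tile = {
            (0, 0): [make_crystal(85.0, 50.0, tile=(0, 0))],
            (0, 1): [make_crystal(5.0, 50.0, tile=(0, 1))],
        }
        kept, index = dedup_overlap(per_tile, mosaic, match_radius_um=2.0)
        assert len(kept) == 1
        assert kept[0].centroid_um == pytest.approx((85.0, 50.0))
        assert index == pytest.approx(0.2)

    def test_zero_overlap_no_drops(self):
        mosaic = self.mosaic(overlap=0.0)
        per_tile = {
            (0, 0): [make_crystal(99.0, 50.0, tile=(0, 0))],
            (0, 1): [make_crystal(1.0, 50.0, tile=(0, 1))],
        }
        kept, index = dedup_overlap(per_tile, mosaic)
        assert len(kept) == 2
        assert index == 0.0

    def test_distinct_crystals_in_strip_both_kept(self):
        mosaic = self.mosaic()
        per_tile = {
            (0, 0): [make_crystal(85.0, 20.0, tile=(0, 0))],
            (0, 1): [make_crystal(5.0, 80.0, tile=(0, 1))],  # 60 um away
        }
        kept, _ = dedup_overlap(per_tile, mosaic, match_radius_um=2.0)
        assert len(kept) == 2

    def test_different_colour_not_merged(self):
        mosaic = self.mosaic()
        per_tile = {
            (0, 0): [make_crystal(85.0, 50.0, "blue", tile=(0, 0))],
            (0, 1): [make_crystal(5.0, 50.0, "red", tile=(0, 1))],
        }
        kept, _ = dedup_overlap(per_tile, mosaic)
        assert len(kept) == 2

    def test_tile_outside_layout(self):
        with pytest.raises(GeometryError):
            dedup_overlap({(0, 5): []}, self.mosaic())


class TestPairDistances:
    def test_three_four_five(self):
        crystals = [make_crystal(0.0, 0.0), make_crystal(3.0, 4.0)]
        stats = pair_distances(crystals, ("blue", "blue"))
        np.testing.assert_allclose(stats.distances_um, [5.0, 5.0])
        assert stats.mean_um == pytest.approx(5.0)
        assert stats.sd_um == 0.0

    def test_single_crystal_error(self):
        with pytest.raises(InsufficientDataError, match="blue"):
            pair_distances([make_crystal(0, 0)], ("blue", "blue"))

    def test_missing_class_error(self):
        with pytest.raises(InsufficientDataError):
            pair_distances([make_crystal(0, 0, "blue")], ("blue", "red"))

    def test_cross_colour_nearest(self):
        crystals = [
            make_crystal(0.0, 0.0, "blue"),
            make_crystal(10.0, 0.0, "red"),
            make_crystal(2.0, 0.0, "red"),
        ]
        stats = pair_distances(crystals, ("blue", "red"))
        np.testing.assert_allclose(stats.distances_um, [2.0])

    def test_all_pairs_symmetric_cross_colour(self):
        rng = np.random.default_rng(5)
        crystals = [
            make_crystal(*xy, colour) for xy, colour in zip(
                rng.uniform(0, 50, size=(20, 2)), ["blue", "red"] * 10
            )
        ]
        ab = pair_distances(crystals, ("blue", "red"), mode="all_pairs")
        ba = pair_distances(crystals, ("red", "blue"), mode="all_pairs")
        np.testing.assert_allclose(ab.distances_um, ba.distances_um)
        assert ab.mean_um == pytest.approx(ba.mean_um)

    def test_all_pairs_count_same_colour(self):
        crystals = [make_crystal(float(i), 0.0) for i in range(5)]
        stats = pair_distances(crystals, ("blue", "blue"), mode="all_pairs")
        assert stats.n == 10  # C(5, 2)

    def test_tile_neighbourhood_excludes_diagonal(self):
        crystals = [
            make_crystal(0.0, 0.0, tile=(0, 0)),
            make_crystal(1.0, 0.0, tile=(1, 1)),  # diagonal: excluded
        ]
        with pytest.raises(InsufficientDataError):
            pair_distances(crystals, ("blue", "blue"))
        off = pair_distances(crystals, ("blue", "blue"), tile_neighbourhood=False)
        np.testing.assert_allclose(off.distances_um, [1.0, 1.0])

    def test_unit_linearity_of_scale(self):
        # halving the pixel size (doubling scale) halves every distance
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:14, 10:14] = True
        mask[40:44, 40:44] = True
        for k in (1.0, 2.0, 4.0):
            found = detect_crystals(mask, 1, scale=k, colour="blue")
            stats = pair_distances(found, ("blue", "blue"))
            base = 30.0 * np.sqrt(2.0)
            assert stats.mean_um == pytest.approx(base / k)

    def test_mean_sd_recomputable(self):
        rng = np.random.default_rng(8)
        crystals = [make_crystal(*xy) for xy in rng.uniform(0, 100, size=(30, 2))]
        stats = pair_distances(crystals, ("blue", "blue"), mode="all_pairs")
        assert stats.mean_um == pytest.approx(stats.distances_um.mean(), abs=1e-9)
        assert stats.sd_um == pytest.approx(stats.distances_um.std(), abs=1e-9)

    def test_poisson_nearest_mean_approaches_theory(self):
        # for a Poisson field of intensity lam the mean NN distance tends to
        # 1 / (2 sqrt(lam)); edge effects bias upward so keep the box large
        lam = 0.01
        side = 400.0
        rng = np.random.default_rng(99)
        n = rng.poisson(lam * side * side)
        pts = rng.uniform(0, side, size=(n, 2))
        crystals = [make_crystal(x, y) for x, y in pts]
        stats = pair_distances(crystals, ("blue", "blue"), tile_neighbourhood=False)
        theory = 1.0 / (2.0 * np.sqrt(lam))
        se = 0.26136 / np.sqrt(n * lam)  # sd of NN distance / sqrt(n)
        assert abs(stats.mean_um - theory) < 4 * se + 0.05 * theory


class TestHistogram:
    def test_single_distance_bin_placement(self):
        crystals = [make_crystal(0.0, 0.0), make_crystal(3.0, 4.0)]
        stats = pair_distances(crystals, ("blue", "blue"), mode="all_pairs")
        counts, edges = distance_histogram(stats, np.linspace(0, 10, 6))
        assert counts.sum() == stats.n == 1
        assert counts[2] == 1  # 5 um falls in the third bin [4, 6)
        assert stats.histogram is not None

    def test_all_equal_distances_single_bin(self):
        crystals = [make_crystal(0.0, 0.0), make_crystal(3.0, 4.0)]
        stats = pair_distances(crystals, ("blue", "blue"))
        counts, _ = distance_histogram(stats, 10)
        assert (counts > 0).sum() == 1
        assert counts.sum() == stats.n

    @given(st.lists(st.floats(0.1, 500.0), min_size=1, max_size=60), st.integers(1, 20))
    @settings(max_examples=40, deadline=None)
    def test_counts_conserved(self, values, bins):
        from artefactscan.crystals import DistancePairStats

        stats = DistancePairStats(
            pair=("a", "a"), mode="all_pairs", distances_um=np.array(values)
        )
        counts, edges = distance_histogram(stats, bins)
        assert counts.sum() == len(values)
        assert len(edges) == len(counts) + 1

    def test_empty_distances_error(self):
        from artefactscan.crystals import DistancePairStats

        stats = DistancePairStats(
            pair=("a", "a"), mode="nearest", distances_um=np.array([])
        )
        with pytest.raises(InsufficientDataError):
            distance_histogram(stats)


class TestDensity:
    def test_paper_packing(self):
        crystals = [make_crystal(float(i), 0.0) for i in range(20)]
        rep = density(crystals, "blue", 2000.0)
        assert rep.count == 20
        assert rep.density == pytest.approx(0.01)

    def test_empty(self):
        assert density([], "blue", 100.0).density == 0.0

    def test_area_scaling(self):
        crystals = [make_crystal(0.0, 0.0)]
        assert density(crystals, "blue", 200.0).density == pytest.approx(
            density(crystals, "blue", 100.0).density / 2.0
        )

    def test_bad_area(self):
        with pytest.raises(ValueError):
            density([], "blue", 0.0)
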