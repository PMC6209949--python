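"""Tile arithmetic, split/stitch round-trips, plot masking, mosaicking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

import weedmap as wm
from weedmap.tiling import PAD_ERROR, PAD_IGNORE

from conftest import random_label_map


class TestCountTiles:
    @pytest.mark.parametrize("w,h,p,expected", [
        (14000, 13000, 1000, 182),  # whole-field ortho-mosaic
        (4000, 3000, 1000, 12),     # one collected image
        (1000, 1000, 1000, 1),
    ])
    def test_exact_division(self, w, h, p, expected):
        assert wm.count_tiles(w, h, p) == expected

    def test_flight_set_total(self):
        # 54 collected images of 4000×3000 → 648 patches
        assert 54 * wm.count_tiles(4000, 3000, 1000) == 648

    def test_padding_rounds_up(self):
        assert wm.count_tiles(1500, 1000, 1000, PAD_IGNORE) == 2

    def test_non_divisible_errors_with_remainders(self):
        with pytest.raises(ValueError, match="width=500"):
            wm.count_tiles(1500, 1000, 1000, PAD_ERROR)

    @given(w=st.integers(1, 50), h=st.integers(1, 50), p=st.integers(1, 12))
    @settings(deadline=None, max_examples=50)
    def test_matches_plan_length(self, w, h, p):
        plan = wm.TilePlan.for_shape(h, w, p)
        assert len(plan) == wm.count_tiles(w, h, p, PAD_IGNORE)


class TestSplitStitch:
    def test_row_major_order_and_count(self, rng):
        labels = random_label_map(rng, 2000 // 10, 3000 // 10)
        plan = wm.TilePlan.for_shape(200, 300, 100)
        tiles = wm.split_raster(labels, plan)
        assert len(tiles) == 6
        assert [t.placement for t in tiles] == [
            (0, 0), (0, 100), (0, 200), (100, 0), (100, 100), (100, 200)]

    @pytest.mark.parametrize("h,w,p", [(200, 300, 100), (150, 100, 100), (64, 64, 64)])
    def test_roundtrip_identity(self, rng, h, w, p):
        labels = random_label_map(rng, h, w)
        plan = wm.TilePlan.for_shape(h, w, p)
        tiles = wm.split_raster(labels, plan)
        out = wm.stitch_labels(tiles, out_shape=(h, w), geo=labels.geo)
        np.testing.assert_array_equal(out.codes, labels.codes)

    def test_padded_label_tile_filled_with_ignore(self, rng):
        labels = random_label_map(rng, 150, 100)
        tiles = wm.split_raster(labels, wm.TilePlan.for_shape(150, 100, 100))
        padded = tiles[1].data  # second row block: 50 real rows
        assert (padded.codes == wm.CODE_IGNORE).sum() == 50 * 100

    def test_image_padding_uses_nodata(self, rng):
        img = wm.GeoRaster(rng.integers(1, 255, (150, 100, 3)).astype(np.uint8),
                           wm.GeoRef(0.005), nodata=0)
        tiles = wm.split_raster(img, wm.TilePlan.for_shape(150, 100, 100))
        assert (tiles[1].data.pixels[50:] == 0).all()

    def test_stitch_order_invariant(self, rng):
        labels = random_label_map(rng, 300, 200)
        tiles = wm.split_raster(labels, wm.TilePlan.for_shape(300, 200, 100))
        perm = rng.permutation(len(tiles))
        out = wm.stitch_labels([tiles[i] for i in perm], out_shape=(300, 200))
        np.testing.assert_array_equal(out.codes, labels.codes)

    def test_stitch_rejects_overlap_and_gap(self, rng):
        a = random_label_map(rng, 100, 100)
        with pytest.raises(ValueError, match="overlapping"):
            wm.stitch_labels([a, a], [(0, 0), (0, 0)], out_shape=(100, 200))
        with pytest.raises(ValueError, match="not covered"):
            wm.stitch_labels([a], [(0, 0)], out_shape=(100, 200))

    def test_tile_geo_metadata_shifts(self, small_scene):
        tiles = wm.split_raster(small_scene.image, wm.TilePlan.for_shape(256, 256, 128))
        g0 = small_scene.image.geo
        t = tiles[3]  # (128, 128)
        assert t.data.geo.origin[0] == pytest.approx(g0.origin[0] + 128 * g0.gsd_m)
        assert t.data.geo.origin[1] == pytest.approx(g0.origin[1] - 128 * g0.gsd_m)


class TestMaskPlot:
    def test_full_extent_polygon_is_identity(self, rng):
        labels = random_label_map(rng, 50, 40)
        h, w, g = 50, 40, labels.gsd_m
        poly = box(0, 0, w * g, h * g)
        out = wm.mask_plot(labels, poly)
        np.testing.assert_array_equal(out.codes, labels.codes)

    def test_half_plane_masks_exactly_half(self, rng):
        labels = random_label_map(rng, 50, 40)
        g = labels.gsd_m
        poly = box(0, 0, 20 * g, 50 * g)  # left half (20 of 40 columns)
        out = wm.mask_plot(labels, poly)
        assert (out.codes[:, 20:] == wm.CODE_IGNORE).all()
        np.testing.assert_array_equal(out.codes[:, :20], labels.codes[:, :20])

    def test_disjoint_polygon_errors(self, rng):
        labels = random_label_map(rng, 50, 40)
        with pytest.raises(ValueError, match="does not intersect"):
            wm.mask_plot(labels, box(100, 100, 200, 200))


class TestMosaicPredictions:
    def _scoremap(self, scores, origin, gsd=0.005):
        return wm.ScoreMap(scores, wm.GeoRef(gsd, origin))

    def test_single_image_equals_own_argmax(self, rng):
        s = self._scoremap(rng.random((20, 30, 3)), (0.0, 1.0))
        out = wm.mosaic_predictions([s])
        np.testing.assert_array_equal(out.codes, np.argmax(s.scores, axis=2))

    def test_identical_scores_in_overlap_agree(self, rng):
        scores = rng.random((20, 20, 3)).astype(np.float32)
        g = 0.005
        a = self._scoremap(scores, (0.0, 20 * g))
        b = self._scoremap(scores[:, 10:], (10 * g, 20 * g))  # right half, shifted
        out = wm.mosaic_predictions([a, b])
        np.testing.assert_array_equal(out.codes, np.argmax(scores, axis=2))

    def test_tied_mean_scores_pick_lowest_code(self):
        scores = np.zeros((4, 4, 3), dtype=np.float32)
        scores[..., 1] = 0.5
        scores[..., 2] = 0.5  # classes 1 and 2 tied, both above 0
        out = wm.mosaic_predictions([self._scoremap(scores, (0.0, 4 * 0.005))])
        assert (out.codes == 1).all()

    def test_uncovered_pixels_are_ignore(self, rng):
        g = 0.005
        a = self._scoremap(rng.random((10, 10, 3)), (0.0, 20 * g))
        b = self._scoremap(rng.random((10, 10, 3)), (10 * g, 10 * g))
        out = wm.mosaic_predictions([a, b])  # two diagonal blocks of a 20×20 field
        assert out.shape == (20, 20)
        assert (out.codes[:10, 10:] == wm.CODE_IGNORE).all()
        assert (out.codes[10:, :10] == wm.CODE_IGNORE).all()

    def test_permutation_invariant(self, rng):
        g = 0.005
        maps = [self._scoremap(rng.random((8, 8, 3)), (i * 4 * g, 8 * g))
                for i in range(3)]
        a = wm.mosaic_predictions(maps)
        b = wm.mosaic_predictions(maps[::-1])
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_inconsistent_gsd_rejected(self, rng):
        a = self._scoremap(rng.random((8, 8, 3)), (0, 0), gsd=0.005)
        b = self._scoremap(rng.random((8, 8, 3)), (0, 0), gsd=0.01)
        with pytest.raises(ValueError, match="gsd"):
            wm.mosaic_predictions([a, b])
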