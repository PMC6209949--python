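"""Chessboard grids, thresholding, prescription accuracy, herbicide saving."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import weedmap as wm
from weedmap.prescription import (
    DEFAULT_THRESHOLDS,
    CoverageGrid,
    PrescriptionMap,
    prescription_to_geojson,
)

from conftest import random_label_map


def label_map(codes, gsd=0.005):
    codes = np.asarray(codes, np.uint8)
    return wm.LabelMap(codes, wm.GeoRef(gsd, (0.0, codes.shape[0] * gsd)))


class TestChessboardCoverage:
    def test_cell_size_in_pixels(self, small_scene):
        # 0.5 m cells at 0.005 m/pixel → 100×100-pixel cells
        grid = wm.chessboard_coverage(small_scene.labels, 0.5)
        assert grid.shape == (3, 3)  # ceil(256/100)

    def test_pure_cells(self):
        codes = np.zeros((200, 100), np.uint8)
        codes[:100] = wm.CODE_WEEDS
        codes[100:] = wm.CODE_RICE
        grid = wm.chessboard_coverage(label_map(codes), 0.5)
        assert grid.values[0, 0] == 1.0 and grid.values[1, 0] == 0.0

    def test_quarter_weed_cell(self):
        codes = np.zeros((100, 100), np.uint8)
        codes[:25] = wm.CODE_WEEDS  # 2500 of 10000 pixels
        grid = wm.chessboard_coverage(label_map(codes), 0.5)
        assert grid.values[0, 0] == pytest.approx(0.25)

    def test_ignore_pixels_excluded_from_denominator(self):
        codes = np.full((100, 100), wm.CODE_IGNORE, np.uint8)
        codes[:50] = wm.CODE_WEEDS
        grid = wm.chessboard_coverage(label_map(codes), 0.5)
        assert grid.values[0, 0] == 1.0

    def test_all_ignore_cell_invalid(self):
        codes = np.full((100, 200), wm.CODE_IGNORE, np.uint8)
        codes[:, :100] = wm.CODE_RICE
        grid = wm.chessboard_coverage(label_map(codes), 0.5)
        assert grid.valid_mask.tolist() == [[True, False]]

    def test_grid_mean_conserves_pixel_coverage(self, rng):
        # pixel-count conservation across the partition: weighted cell mean
        # equals the field-level coverage to ~1e-9
        labels = random_label_map(rng, 700, 500)
        grid = wm.chessboard_coverage(labels, 0.5)
        codes = labels.codes
        blocks_w = np.zeros(grid.shape)
        blocks_n = np.zeros(grid.shape)
        for r in range(grid.shape[0]):
            for c in range(grid.shape[1]):
                blk = codes[r * 100:(r + 1) * 100, c * 100:(c + 1) * 100]
                blocks_w[r, c] = (blk == wm.CODE_WEEDS).sum()
                blocks_n[r, c] = (blk != wm.CODE_IGNORE).sum()
        total = (grid.values * blocks_n).sum() / blocks_n.sum()
        expected = (codes == wm.CODE_WEEDS).sum() / (codes != wm.CODE_IGNORE).sum()
        assert total == pytest.approx(expected, abs=1e-9)

    def test_non_integer_cell_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            wm.chessboard_coverage(label_map(np.zeros((10, 10)), gsd=0.003), 0.5)


class TestApplyThreshold:
    def test_strict_inequality_at_zero(self):
        grid = CoverageGrid(np.array([[0.0, 0.01]]), np.ones((1, 2), bool),
                            0.5, wm.GeoRef(0.005))
        pm = wm.apply_threshold(grid, 0.0)
        assert pm.treatment.tolist() == [[False, True]]

    def test_strictness_at_boundary(self):
        grid = CoverageGrid(np.array([[0.05, 0.06]]), np.ones((1, 2), bool),
                            0.5, wm.GeoRef(0.005))
        pm = wm.apply_threshold(grid, 0.05)
        assert pm.treatment.tolist() == [[False, True]]

    def test_out_of_range_threshold_rejected(self):
        grid = CoverageGrid(np.zeros((1, 1)), np.ones((1, 1), bool), 0.5, wm.GeoRef(1.0))
        with pytest.raises(ValueError, match="threshold"):
            wm.apply_threshold(grid, 1.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_raising_threshold_never_adds_treatment(self, seed):
        rng = np.random.default_rng(seed)
        grid = CoverageGrid(rng.random((6, 6)), np.ones((6, 6), bool),
                            0.5, wm.GeoRef(0.005))
        taus = sorted(rng.random(4))
        maps = [wm.apply_threshold(grid, t).treatment for t in taus]
        for lo, hi in zip(maps, maps[1:]):
            assert not (hi & ~lo).any()


def make_pmap(treated, total, threshold=0.0):
    t = np.zeros(total, bool)
    t[:treated] = True
    shape = (1, total)
    return PrescriptionMap(t.reshape(shape), np.ones(shape, bool), threshold,
                           0.5, wm.GeoRef(0.005))


class TestAccuracyAndSaving:
    def test_identical_maps_perfect_accuracy(self):
        a = make_pmap(400, 1000)
        assert wm.prescription_accuracy(a, a) == 1.0

    def test_one_cell_difference(self):
        grid = lambda v: CoverageGrid(v, np.ones((3, 3), bool), 0.5, wm.GeoRef(0.005))
        a = wm.apply_threshold(grid(np.full((3, 3), 0.4)), 0.1)
        vals = np.full((3, 3), 0.4)
        vals[0, 0] = 0.0
        b = wm.apply_threshold(grid(vals), 0.1)
        assert wm.prescription_accuracy(a, b) == pytest.approx(8 / 9)

    def test_matches_cell_loop_oracle(self, rng):
        shape = (7, 9)
        geo = wm.GeoRef(0.005)
        valid = rng.random(shape) > 0.1
        a = PrescriptionMap(rng.random(shape) > 0.5, valid, 0.1, 0.5, geo)
        b = PrescriptionMap(rng.random(shape) > 0.5, valid, 0.1, 0.5, geo)
        match = total = 0
        for r in range(shape[0]):
            for c in range(shape[1]):
                if valid[r, c]:
                    total += 1
                    match += a.treatment[r, c] == b.treatment[r, c]
        assert wm.prescription_accuracy(a, b) == pytest.approx(match / total)

    def test_threshold_mismatch_rejected(self):
        with pytest.raises(ValueError, match="[Tt]hreshold"):
            wm.prescription_accuracy(make_pmap(1, 10, 0.0), make_pmap(1, 10, 0.1))

    def test_treatment_fraction_counts_valid_cells(self):
        assert wm.treatment_fraction(make_pmap(417, 1000)) == pytest.approx(0.417)
        assert wm.treatment_fraction(make_pmap(1000, 1000)) == 1.0

    def test_saving_is_complement(self):
        pm = make_pmap(417, 1000)
        assert wm.herbicide_saving(pm) == pytest.approx(0.583)
        assert wm.herbicide_saving(pm) + wm.treatment_fraction(pm) == pytest.approx(1.0)

    def test_empty_treatment_full_saving(self):
        assert wm.herbicide_saving(make_pmap(0, 10)) == 1.0


class TestSweep:
    def test_default_thresholds(self):
        assert DEFAULT_THRESHOLDS == (0.00, 0.05, 0.10, 0.15, 0.20, 0.25)

    def test_perfect_prediction_all_accuracies_one(self, small_scene):
        sweep = wm.sweep_thresholds(small_scene.labels, small_scene.labels)
        assert (sweep.accuracy == 1.0).all()
        assert list(sweep.threshold) == list(DEFAULT_THRESHOLDS)

    def test_treatment_fraction_non_increasing(self, rng):
        pred = random_label_map(rng, 700, 500)
        gt = random_label_map(rng, 700, 500)
        sweep = wm.sweep_thresholds(pred, gt)
        tf = sweep.treatment_fraction.to_numpy()
        assert (np.diff(tf) <= 1e-12).all()

    def test_saving_complements_treatment(self, rng):
        sweep = wm.sweep_thresholds(random_label_map(rng, 300, 300),
                                    random_label_map(rng, 300, 300))
        np.testing.assert_allclose(
            sweep.treatment_fraction + sweep.herbicide_saving, 1.0)


class TestGeoJSON:
    def test_cells_and_properties(self):
        grid = CoverageGrid(np.array([[0.2, 0.0]]), np.array([[True, False]]),
                            0.5, wm.GeoRef(0.005, (10.0, 20.0)))
        pm = wm.apply_threshold(grid, 0.1)
        gj = prescription_to_geojson(pm, grid)
        assert len(gj["features"]) == 1  # invalid cell skipped
        f = gj["features"][0]
        assert f["properties"] == {"treatment": True, "coverage": 0.2}
        xs = [p[0] for p in f["geometry"]["coordinates"][0]]
        assert min(xs) == 10.0 and max(xs) == 10.5
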