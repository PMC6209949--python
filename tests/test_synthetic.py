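"""Synthetic field generator: determinism, coverage control, geometry."""

import dataclasses

import numpy as np
import pytest

import weedmap as wm
from weedmap.synthetic import load_manifest, realized_weed_coverage


class TestGenerateScene:
    def test_deterministic_for_identical_spec(self):
        spec = wm.FieldSpec(128, 96, seed=7)
        a, b = wm.generate_scene(spec), wm.generate_scene(spec)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.labels.codes, b.labels.codes)

    def test_different_seed_changes_scene(self):
        spec = wm.FieldSpec(128, 96, seed=7)
        other = wm.generate_scene(dataclasses.replace(spec, seed=8))
        base = wm.generate_scene(spec)
        assert (base.labels.codes != other.labels.codes).any()

    def test_zero_target_gives_no_weed_pixels(self):
        scene = wm.generate_scene(wm.FieldSpec(200, 200, target_weed_coverage=0.0, seed=1))
        assert (scene.labels.codes == wm.CODE_WEEDS).sum() == 0

    @pytest.mark.parametrize("target", [0.1, 0.3, 0.5])
    def test_realized_coverage_tracks_target(self, target):
        scene = wm.generate_scene(
            wm.FieldSpec(500, 500, target_weed_coverage=target, seed=3))
        assert realized_weed_coverage(scene.labels) == pytest.approx(target, abs=0.03)

    def test_nonveg_fraction_respected(self):
        scene = wm.generate_scene(wm.FieldSpec(400, 400, nonveg_coverage=0.10, seed=2))
        frac = (scene.labels.codes == wm.CODE_OTHERS).mean()
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_class_mean_colors_pairwise_distinct(self, small_scene):
        means = {
            c: small_scene.image.pixels[small_scene.labels.codes == c].mean(axis=0)
            for c in (wm.CODE_OTHERS, wm.CODE_RICE, wm.CODE_WEEDS)
        }
        codes = list(means)
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                assert np.linalg.norm(means[a] - means[b]) > 30.0

    def test_image_and_labels_share_geometry(self, small_scene):
        assert small_scene.image.shape == small_scene.labels.shape
        assert small_scene.image.geo == small_scene.labels.geo

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(width_px=0, height_px=10), "width_px"),
        (dict(width_px=10, height_px=10, target_weed_coverage=1.2), "target_weed_coverage"),
        (dict(width_px=10, height_px=10, nonveg_coverage=1.0), "nonveg_coverage"),
        (dict(width_px=10, height_px=10, target_weed_coverage=0.7, nonveg_coverage=0.4),
         "nonveg_coverage"),
    ])
    def test_invalid_spec_names_offending_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            wm.FieldSpec(**kwargs)


class TestFlightSet:
    def test_zero_overlap_tiles_field_exactly(self):
        spec = wm.FieldSpec(240, 160, seed=5)
        scenes = wm.generate_flight_set(spec, 4, 0.0, 0.0)
        master = wm.generate_scene(spec)
        assembled = np.full(master.labels.shape, 255, np.uint8)
        covered = np.zeros(master.labels.shape, bool)
        for s in scenes:
            r, c = s.labels.geo.pixel_offset_from(master.labels.geo)
            h, w = s.labels.shape
            assembled[r:r + h, c:c + w] = s.labels.codes
            covered[r:r + h, c:c + w] = True
        assert covered.all()
        np.testing.assert_array_equal(assembled, master.labels.codes)

    def test_forward_overlap_fraction_of_consecutive_footprints(self):
        spec = wm.FieldSpec(1000, 200, seed=5)
        scenes = wm.generate_flight_set(spec, 20, 0.7, 0.0, image_size_px=(200, 200))
        master = wm.generate_scene(spec)
        offs = [s.labels.geo.pixel_offset_from(master.labels.geo) for s in scenes]
        cols = sorted({c for _, c in offs})
        for a, b in zip(cols, cols[1:-1]):  # last window is edge-clamped
            shared = 200 - (b - a)
            assert abs(shared - 0.7 * 200) <= 1

    def test_overlapping_pixels_identical_labels(self):
        spec = wm.FieldSpec(300, 300, seed=9)
        scenes = wm.generate_flight_set(spec, 9, 0.5, 0.5, image_size_px=(150, 150))
        master = wm.generate_scene(spec)
        for s in scenes:
            r, c = s.labels.geo.pixel_offset_from(master.labels.geo)
            h, w = s.labels.shape
            np.testing.assert_array_equal(
                s.labels.codes, master.labels.codes[r:r + h, c:c + w])

    def test_insufficient_images_error_states_minimum(self):
        spec = wm.FieldSpec(240, 160, seed=5)
        with pytest.raises(ValueError, match="minimum is 4"):
            wm.generate_flight_set(spec, 3, 0.0, 0.0)

    def test_overlap_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="overlap_forward"):
            wm.generate_flight_set(wm.FieldSpec(100, 100), 4, 0.99, 0.0)


class TestGenerateDataset:
    def test_manifest_roles_and_roundtrip(self, tmp_path):
        s1 = wm.FieldSpec(64, 64, seed=1)
        s2 = dataclasses.replace(s1, seed=2, appearance_shift=0.4)
        manifest = wm.generate_dataset(s1, s2, tmp_path)
        assert list(manifest.role) == ["train", "valtest"]
        reloaded = load_manifest(tmp_path)
        assert reloaded.to_dict() == manifest.to_dict()

    def test_written_scenes_reload_identically(self, tmp_path):
        s1 = wm.FieldSpec(64, 64, seed=1)
        s2 = dataclasses.replace(s1, seed=2)
        wm.generate_dataset(s1, s2, tmp_path)
        img = wm.read_image(tmp_path / "date1_image.png")
        lab = wm.read_labels(tmp_path / "date1_labels.png")
        scene = wm.generate_scene(s1)
        np.testing.assert_array_equal(img.pixels, scene.image.pixels)
        np.testing.assert_array_equal(lab.codes, scene.labels.codes)
        assert img.geo.origin == pytest.approx(scene.image.geo.origin)

    def test_no_appearance_shift_keeps_channel_means_close(self):
        s1 = wm.FieldSpec(400, 400, seed=1)
        s2 = dataclasses.replace(s1, seed=2, appearance_shift=0.0)
        m1 = wm.generate_scene(s1).image.pixels.mean(axis=(0, 1))
        m2 = wm.generate_scene(s2).image.pixels.mean(axis=(0, 1))
        np.testing.assert_allclose(m1, m2, rtol=0.01)

    def test_specs_differing_beyond_seed_and_shift_rejected(self, tmp_path):
        s1 = wm.FieldSpec(64, 64, seed=1)
        s2 = wm.FieldSpec(64, 64, seed=2, target_weed_coverage=0.5)
        with pytest.raises(ValueError, match="seed and appearance_shift"):
            wm.generate_dataset(s1, s2, tmp_path)
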