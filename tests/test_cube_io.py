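"""Calibration, segmentation, ROI spectra, band cropping, ENVI round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specseed.cube import (
    CalibrationError,
    CalibrationPair,
    HyperCube,
    RoiMask,
    calibrate_reflectance,
    crop_bands,
    drop_first_bands,
    extract_mean_spectra,
    segment_seeds,
)
from specseed.envi import read_envi, write_envi
from specseed.grid import WavelengthGrid
from specseed.synthetic import SyntheticConfig, generate_dataset, generate_reference_cube


def _cube(data, grid=None, kind="raw"):
    grid = grid or WavelengthGrid(np.linspace(900, 1700, data.shape[2]))
    return HyperCube(np.asarray(data, dtype=float), grid, kind)


class TestCalibration:
    def setup_method(self):
        self.white = np.full((5, 5, 4), 4000.0)
        self.dark = np.full((5, 5, 4), 100.0)
        self.pair = CalibrationPair(self.white, self.dark)

    def test_raw_equal_white_gives_unit_reflectance(self):
        out = calibrate_reflectance(_cube(self.white), self.pair)
        assert np.allclose(out.data, 1.0) and out.kind == "reflectance"

    def test_raw_equal_dark_gives_zero(self):
        out = calibrate_reflectance(_cube(self.dark), self.pair)
        assert np.allclose(out.data, 0.0)

    def test_midpoint_gives_half(self):
        out = calibrate_reflectance(_cube((self.white + self.dark) / 2), self.pair)
        assert np.allclose(out.data, 0.5)

    def test_bad_reference_error_reports_pixel_count(self):
        white = self.white.copy()
        white[0, 0, :2] = 50.0  # below dark at 2 positions
        with pytest.raises(CalibrationError, match="2 cube positions"):
            calibrate_reflectance(_cube(self.dark + 1), CalibrationPair(white, self.dark))

    @given(gain=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance_under_common_gain(self, gain):
        rng = np.random.default_rng(0)
        raw = rng.uniform(200, 3000, (5, 5, 4))
        a = calibrate_reflectance(_cube(raw), self.pair)
        b = calibrate_reflectance(
            _cube(raw * gain),
            CalibrationPair(self.white * gain, self.dark * gain),
        )
        assert np.allclose(a.data, b.data, atol=1e-9)

    def test_monotone_in_raw_counts(self):
        raw = np.full((5, 5, 4), 1000.0)
        lo = calibrate_reflectance(_cube(raw), self.pair)
        hi = calibrate_reflectance(_cube(raw + 250), self.pair)
        assert np.all(hi.data > lo.data)


class TestSegmentation:
    def test_uniform_cube_below_threshold_no_objects(self):
        cube = _cube(np.full((20, 20, 3), 0.1), kind="reflectance")
        mask = segment_seeds(cube, threshold_rule=0.5)
        assert mask.n_objects == 0

    def test_raw_cube_rejected(self):
        with pytest.raises(ValueError, match="reflectance"):
            segment_seeds(_cube(np.zeros((4, 4, 3))))

    def test_noise_free_scene_mask_matches_planted_exactly(self, toy_grid):
        scene = generate_reference_cube((60, 60, ), toy_grid, 4, layout=(2, 2))
        refl = calibrate_reflectance(
            scene.raw, CalibrationPair(scene.white.data, scene.dark.data)
        )
        mask = segment_seeds(refl, min_area=5)
        assert np.array_equal(mask.labels, scene.true_mask.labels)

    def test_42_planted_objects_found(self, toy_grid):
        scene = generate_reference_cube((140, 120), toy_grid, 42, layout=(7, 6))
        refl = calibrate_reflectance(
            scene.raw, CalibrationPair(scene.white.data, scene.dark.data)
        )
        assert segment_seeds(refl, min_area=5).n_objects == 42


class TestExtraction:
    def test_single_pixel_object_returns_that_spectrum(self, toy_grid):
        data = np.random.default_rng(0).uniform(0, 1, (4, 4, 10))
        labels = np.zeros((4, 4), dtype=int)
        labels[2, 3] = 1
        ds = extract_mean_spectra(_cube(data, toy_grid, "reflectance"), RoiMask(labels))
        assert np.allclose(ds.X[0], data[2, 3])

    def test_constant_cube_gives_constant_spectra(self, toy_grid):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:3, 1:3] = 1
        labels[4:6, 4:6] = 2
        ds = extract_mean_spectra(
            _cube(np.full((6, 6, 10), 0.3), toy_grid, "reflectance"), RoiMask(labels)
        )
        assert ds.n_samples == 2 and np.allclose(ds.X, 0.3)

    def test_two_pixel_object_arithmetic_mean(self, toy_grid):
        data = np.zeros((2, 2, 10))
        data[0, 0] = 0.2
        data[0, 1] = 0.4
        labels = np.zeros((2, 2), dtype=int)
        labels[0, :2] = 1
        ds = extract_mean_spectra(_cube(data, toy_grid, "reflectance"), RoiMask(labels))
        assert np.allclose(ds.X[0], 0.3)

    def test_segment_extract_recovers_planted_spectra(self, toy_grid):
        scene = generate_reference_cube((60, 60), toy_grid, 4, layout=(2, 2))
        refl = calibrate_reflectance(
            scene.raw, CalibrationPair(scene.white.data, scene.dark.data)
        )
        mask = segment_seeds(refl, min_area=5)
        ds = extract_mean_spectra(refl, mask)
        assert np.allclose(ds.X, scene.planted_spectra, atol=1e-9)

    def test_extract_commutes_with_calibration_for_flat_references(self, toy_grid):
        """Mean-then-calibrate equals calibrate-then-mean when references are
        spatially constant (the affine map commutes with averaging)."""
        rng = np.random.default_rng(1)
        raw = rng.uniform(500, 3000, (8, 8, 10))
        white = np.full((8, 8, 10), 4000.0)
        dark = np.full((8, 8, 10), 100.0)
        labels = np.zeros((8, 8), dtype=int)
        labels[2:5, 2:5] = 1
        cal = CalibrationPair(white, dark)
        a = extract_mean_spectra(
            calibrate_reflectance(_cube(raw, toy_grid), cal), RoiMask(labels)
        ).X[0]
        mean_raw = extract_mean_spectra(
            _cube(raw, toy_grid, "reflectance"), RoiMask(labels)
        ).X[0]
        b = (mean_raw - 100.0) / (4000.0 - 100.0)
        assert np.allclose(a, b, atol=1e-12)


class TestCropBands:
    def test_drop_first_9_of_254_leaves_245(self):
        ds = generate_dataset(SyntheticConfig(n_per_class=2, seed=0))
        out = drop_first_bands(ds, 9)
        assert out.n_bands == 245
        assert out.wavelengths[0] == ds.wavelengths[9]

    def test_full_range_crop_is_identity(self, toy_grid):
        ds = generate_dataset(
            SyntheticConfig(n_per_class=2, grid=toy_grid, seed=0)
        )
        out = crop_bands(ds, ds.wavelengths[0], ds.wavelengths[-1])
        assert np.array_equal(out.X, ds.X)

    def test_toy_crop_at_third_wavelength(self, toy_grid):
        ds = generate_dataset(
            SyntheticConfig(n_per_class=2, grid=toy_grid, seed=0)
        )
        out = crop_bands(ds, ds.wavelengths[2], ds.wavelengths[-1])
        assert out.n_bands == 8

    def test_empty_crop_rejected(self, toy_grid):
        ds = generate_dataset(SyntheticConfig(n_per_class=2, grid=toy_grid, seed=0))
        with pytest.raises(ValueError):
            crop_bands(ds, 100.0, 200.0)
        with pytest.raises(ValueError):
            crop_bands(ds, 1500.0, 1000.0)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil"])
    def test_roundtrip(self, tmp_path, toy_grid, interleave):
        rng = np.random.default_rng(2)
        cube = _cube(rng.uniform(0, 1, (7, 5, 10)), toy_grid)
        path = tmp_path / "scene.raw"
        write_envi(cube, path, interleave=interleave)
        back = read_envi(path)
        assert np.allclose(back.data, cube.data, atol=1e-6)
        assert np.allclose(back.grid.values, toy_grid.values, atol=1e-3)

    def test_missing_header_raises(self, tmp_path):
        p = tmp_path / "orphan.raw"
        p.write_bytes(b"\x00" * 16)
        with pytest.raises(FileNotFoundError):
            read_envi(p)
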