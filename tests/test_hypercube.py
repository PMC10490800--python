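import numpy as np
import pytest

from pellspec import synthetic
from pellspec.core import SpectraSet, WavelengthGrid, default_grid
from pellspec.hypercube import (
    EnviError,
    NoSampleError,
    RawCube,
    ReflectanceCube,
    correct_reflectance,
    mean_spectrum,
    pixel_spectra,
    read_envi,
    segment_sample,
    trim_bands,
    write_envi,
)


def _cube(rows=4, cols=5, bands=6, seed=0) -> RawCube:
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(np.linspace(1000.0, 1000.0 + 10 * (bands - 1), bands))
    return RawCube(rng.uniform(100, 4000, (rows, cols, bands)), grid)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    def test_round_trip_identity(self, tmp_path, interleave):
        cube = _cube()
        write_envi(cube, tmp_path / "c.hdr", tmp_path / "c.dat", interleave)
        back = read_envi(tmp_path / "c.hdr", tmp_path / "c.dat")
        np.testing.assert_allclose(back.data, cube.data, rtol=1e-6)
        np.testing.assert_allclose(back.grid.wavelengths, cube.grid.wavelengths)

    def test_interleave_equivalence(self, tmp_path):
        cube = _cube(seed=3)
        reads = []
        for il in ("bil", "bsq"):
            write_envi(cube, tmp_path / f"{il}.hdr", tmp_path / f"{il}.dat", il)
            reads.append(read_envi(tmp_path / f"{il}.hdr", tmp_path / f"{il}.dat"))
        np.testing.assert_array_equal(reads[0].data, reads[1].data)

    def test_size_mismatch_rejected(self, tmp_path):
        cube = _cube()
        write_envi(cube, tmp_path / "c.hdr", tmp_path / "c.dat")
        hdr = (tmp_path / "c.hdr").read_text().replace("bands = 6", "bands = 7")
        hdr = hdr.replace(
            "wavelength = {", "wavelength = { 999.0,"
        )
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(EnviError, match="binary holds"):
            read_envi(tmp_path / "c.hdr", tmp_path / "c.dat")

    def test_missing_wavelengths_rejected(self, tmp_path):
        cube = _cube()
        write_envi(cube, tmp_path / "c.hdr", tmp_path / "c.dat")
        lines = [
            l
            for l in (tmp_path / "c.hdr").read_text().splitlines()
            if not l.startswith("wavelength =")
        ]
        (tmp_path / "c.hdr").write_text("\n".join(lines))
        with pytest.raises(EnviError, match="wavelength"):
            read_envi(tmp_path / "c.hdr", tmp_path / "c.dat")


class TestReflectanceCorrection:
    def test_calibration_identities(self):
        raw = _cube(seed=1)
        dark = RawCube(np.full(raw.shape, 50.0), raw.grid)
        white = RawCube(np.full(raw.shape, 3000.0), raw.grid)
        ones = correct_reflectance(white, dark, white)
        np.testing.assert_allclose(ones.data[ones.valid_mask], 1.0)
        zeros = correct_reflectance(dark, dark, white)
        np.testing.assert_allclose(zeros.data[zeros.valid_mask], 0.0)
        mid = RawCube((dark.data + white.data) / 2, raw.grid)
        half = correct_reflectance(mid, dark, white)
        np.testing.assert_allclose(half.data[half.valid_mask], 0.5)

    def test_common_gain_invariance(self):
        raw = _cube(seed=2)
        dark = RawCube(np.full(raw.shape, 80.0), raw.grid)
        white = RawCube(np.full(raw.shape, 3500.0), raw.grid)
        a = correct_reflectance(raw, dark, white)
        b = correct_reflectance(
            RawCube(raw.data * 2.5, raw.grid),
            RawCube(dark.data * 2.5, raw.grid),
            RawCube(white.data * 2.5, raw.grid),
        )
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_degenerate_pixels_masked_not_clamped(self):
        raw = _cube()
        dark = np.full(raw.shape, 100.0)
        white = np.full(raw.shape, 3000.0)
        white[1, 2, :] = 50.0  # white below dark: uncalibratable pixel
        out = correct_reflectance(raw, dark, white)
        assert not out.valid_mask[1, 2]
        assert out.valid_mask.sum() == raw.shape[0] * raw.shape[1] - 1
        assert np.all(np.isfinite(out.data))

    def test_fully_degenerate_rejected(self):
        raw = _cube()
        with pytest.raises(ValueError, match="degenerate"):
            correct_reflectance(
                raw, np.full(raw.shape, 10.0), np.full(raw.shape, 5.0)
            )


class TestSegmentation:
    @pytest.fixture(scope="class")
    def scene(self):
        refs = synthetic.generate_reference_values(8, (8, 14), 0.0, seed=5)
        cfg = synthetic.SimulationConfig(n_samples=8, seed=5)
        raw, dark, white, gt = synthetic.generate_scene(
            refs, default_grid(), cfg, (80, 100)
        )
        return correct_reflectance(raw, dark, white), gt

    def test_recovers_truth_mask(self, scene):
        cube, gt = scene
        mask = segment_sample(cube)
        iou = (mask & gt.sample_mask).sum() / (mask | gt.sample_mask).sum()
        assert iou >= 0.95

    def test_uniform_image_raises(self):
        grid = WavelengthGrid(np.linspace(1000, 1050, 6))
        cube = ReflectanceCube(
            np.full((10, 10, 6), 0.5), grid, np.ones((10, 10), bool)
        )
        with pytest.raises(NoSampleError):
            segment_sample(cube)

    def test_mask_area_monotone_in_component_size(self, scene):
        cube, _ = scene
        areas = [
            segment_sample(cube, min_component_size=s).sum() for s in (1, 20, 200)
        ]
        assert areas[0] >= areas[1] >= areas[2]


class TestMeanSpectrum:
    def _refl(self, data):
        grid = WavelengthGrid(np.array([1000.0, 1010.0]))
        return ReflectanceCube(data, grid, np.ones(data.shape[:2], bool))

    def test_arithmetic_mean(self):
        data = np.zeros((1, 2, 2))
        data[0, 0] = [1.0, 3.0]
        data[0, 1] = [3.0, 5.0]
        cube = self._refl(data)
        np.testing.assert_allclose(
            mean_spectrum(cube, np.ones((1, 2), bool)), [2.0, 4.0]
        )

    def test_single_pixel_identity(self):
        data = np.arange(12, dtype=float).reshape(2, 3, 2)
        cube = self._refl(data)
        mask = np.zeros((2, 3), bool)
        mask[1, 2] = True
        np.testing.assert_array_equal(mean_spectrum(cube, mask), data[1, 2])

    def test_empty_or_invalid_mask_rejected(self):
        cube = self._refl(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            mean_spectrum(cube, np.zeros((2, 2), bool))
        cube.valid_mask[0, 0] = False
        with pytest.raises(ValueError, match="invalid"):
            mean_spectrum(cube, np.ones((2, 2), bool))

    def test_scene_mean_close_to_pixel_level(self):
        refs = synthetic.generate_reference_values(4, (8, 14), 0.0, seed=9)
        cfg = synthetic.SimulationConfig(n_samples=4, seed=9)
        raw, dark, white, gt = synthetic.generate_scene(
            refs, default_grid(), cfg, (40, 50), spatial_sd=0.0
        )
        cube = correct_reflectance(raw, dark, white)
        ms = mean_spectrum(cube, gt.sample_mask)
        px = pixel_spectra(cube, gt.sample_mask).matrix
        # identical underlying spectrum + iid channel noise per pixel
        assert np.max(np.abs(px - ms[None, :])) < 6 * cfg.noise_sd


class TestTrimBands:
    def test_edge_trim_retains_244_bands(self, grid256):
        s = SpectraSet(np.zeros((2, 256)), grid256, ["a", "b"])
        out = trim_bands(s, 960.0, 2489.0)
        assert out.n_bands == 244
        assert out.grid.wavelengths[0] >= 960.0
        assert out.grid.wavelengths[-1] <= 2489.0

    def test_full_span_identity_and_idempotence(self, small_set):
        lo, hi = small_set.grid.span()
        once = trim_bands(small_set, lo, hi)
        np.testing.assert_array_equal(once.matrix, small_set.matrix)
        twice = trim_bands(trim_bands(small_set, 1005, 1065), 1005, 1065)
        np.testing.assert_array_equal(
            twice.matrix, trim_bands(small_set, 1005, 1065).matrix
        )

    def test_closed_interval_rule(self):
        grid = WavelengthGrid(np.array([100.0, 110.0, 120.0, 130.0, 140.0]))
        s = SpectraSet(np.arange(10, dtype=float).reshape(2, 5), grid, ["a", "b"])
        out = trim_bands(s, 105, 135)
        np.testing.assert_array_equal(out.grid.wavelengths, [110.0, 120.0, 130.0])

    def test_commutes_with_mean_spectrum(self):
        rng = np.random.default_rng(4)
        grid = WavelengthGrid(np.linspace(1000, 1100, 11))
        data = rng.uniform(0.1, 0.9, (3, 4, 11))
        cube = ReflectanceCube(data, grid, np.ones((3, 4), bool))
        mask = np.ones((3, 4), bool)
        a = mean_spectrum(cube, mask)[2:8]
        as_set = SpectraSet(a[None, :], WavelengthGrid(grid.wavelengths[2:8]), ["m"])
        full = SpectraSet(mean_spectrum(cube, mask)[None, :], grid, ["m"])
        b = trim_bands(full, grid.wavelengths[2], grid.wavelengths[7])
        np.testing.assert_allclose(as_set.matrix, b.matrix)

    def test_empty_interval_rejected(self, small_set):
        with pytest.raises(ValueError):
            trim_bands(small_set, 2000.0, 3000.0)
        with pytest.raises(ValueError):
            trim_bands(small_set, 1090.0, 1000.0)
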